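"""Independent exact-rational oracle for Fisher's exact test on 2x2 tables.

Enumerates the full hypergeometric outcome space with Fraction
arithmetic, entirely independent of the scipy-backed implementation the
package uses.
"""

from fractions import Fraction
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int, alternative: str) -> Fraction:
    """Exact p-value by exhaustive enumeration of tables with fixed margins.

    ``alternative`` is "greater" (upper tail in the top-left cell) or
    "two-sided" (sum of outcomes no more probable than the observed one).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return Fraction(1)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    den = comb(n, r1)

    def num(x: int) -> int:
        return comb(c1, x) * comb(n - c1, r1 - x)

    if alternative == "greater":
        total = sum(num(x) for x in range(a, hi + 1))
    elif alternative == "two-sided":
        na = num(a)
        total = sum(num(x) for x in range(lo, hi + 1) if num(x) <= na)
    else:
        raise ValueError(alternative)
    return Fraction(total, den)
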