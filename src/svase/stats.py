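"""Exact-test helpers shared by the junction, variant and association filters.

All four statistical gates in the pipeline (junction background expression,
variant significance, allele-frequency consistency, variant-junction
association) reduce to Fisher's exact test on a 2x2 contingency table; the
table constructions differ and live with their callers.
"""

from __future__ import annotations

import math

from scipy.stats import fisher_exact


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the table [[a, b], [c, d]].

    Tests enrichment of column 1 in row 1 against the hypergeometric null.
    """
    return float(fisher_exact([[a, b], [c, d]], alternative="greater").pvalue)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (sum of outcomes no more probable than observed)."""
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def passes_alpha(p: float, alpha: float) -> bool:
    """Significance gate ``p <= alpha``, robust to float round-off.

    Exact-test p-values are rationals; a table sitting exactly on the
    threshold (e.g. p = 1/20 at alpha 0.05) must pass even when the float
    computation lands a few ulp above it.
    """
    return p <= alpha or math.isclose(p, alpha, rel_tol=1e-9, abs_tol=1e-12)
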