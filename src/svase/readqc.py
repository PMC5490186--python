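"""Rule-based read quality control applied before any junction or variant logic.

Alignment records are screened with a fixed sequence of stringent filters:
unmapped and non-primary records, PCR duplicates, platform QC failures,
improperly paired reads (for paired-end data), reads carrying insertions or
deletions, reads with excess mismatches, short reads (< 30 bp) and reads
with low mean base quality (< Q30) are all removed.  Checks run in a fixed
order so rejection tallies are deterministic.

Base quality plays a dual role: the whole-read mean gates the read itself,
and individual bases below the threshold are masked so that downstream
pileups never count error-prone calls, while the read still supports its
junction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

# CIGAR operation classes (SAM operation characters)
CONSUMES_QUERY = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")
ALIGN_OPS = frozenset("M=X")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass
class AlignedRead:
    """One alignment record plus the state QC attaches to it.

    Coordinates are 0-based; ``cigar`` is a tuple of ``(op, length)`` pairs
    using SAM operation characters.  ``mask`` is filled in by
    :func:`filter_alignments`: a boolean array aligned with ``seq`` marking
    bases whose quality falls below the masking threshold.
    """

    read_id: str
    chrom: Optional[str]
    pos: int
    cigar: tuple
    seq: str
    base_quals: tuple
    mapq: int = 60
    flag: int = 0
    mismatch_count: Optional[int] = None
    mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_qcfail(self) -> bool:
        return bool(self.flag & FLAG_QCFAIL)

    # -- geometry helpers ---------------------------------------------
    @property
    def query_length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in CONSUMES_QUERY)
        if qlen != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.seq)}"
            )
        if len(self.seq) != len(self.base_quals):
            raise ValueError(f"read {self.read_id}: |seq| != |base_quals|")

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in CONSUMES_REF)

    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.cigar)

    def has_gap(self) -> bool:
        return any(op == "N" for op, _ in self.cigar)

    def aligned_pairs(self) -> Iterator[tuple]:
        """Yield (query_index, reference_position) for every aligned base."""
        q, r = 0, self.pos
        for op, n in self.cigar:
            if op in ALIGN_OPS:
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            else:
                if op in CONSUMES_QUERY:
                    q += n
                if op in CONSUMES_REF:
                    r += n

    def blocks(self) -> list:
        """Aligned reference blocks [(ref_start, ref_end), ...], N/D splits merged
        only over insertions (which do not consume reference)."""
        out = []
        r = self.pos
        cur_start = None
        for op, n in self.cigar:
            if op in ALIGN_OPS:
                if cur_start is None:
                    cur_start = r
                r += n
            elif op in "DN":
                if cur_start is not None:
                    out.append((cur_start, r))
                    cur_start = None
                r += n
        if cur_start is not None:
            out.append((cur_start, r))
        return out

    def base_at(self, rpos: int):
        """Return (base, qual, query_index) aligned at reference position rpos,
        or None if the read has no aligned base there."""
        q, r = 0, self.pos
        for op, n in self.cigar:
            if op in ALIGN_OPS:
                if r <= rpos < r + n:
                    qi = q + (rpos - r)
                    return self.seq[qi], self.base_quals[qi], qi
                q += n
                r += n
            else:
                if op in CONSUMES_QUERY:
                    q += n
                if op in CONSUMES_REF:
                    if r <= rpos < r + n:
                        return None
                    r += n
        return None


@dataclass
class QcParams:
    """Thresholds for the rule-based read filters.

    min_base_qual gates both the whole-read mean quality and the per-base
    mask; min_mapq implements the multi-mapper floor (primary alignments at
    or below a multi-mapper sentinel MAPQ are discarded).
    """

    min_base_qual: int = 30
    min_read_len: int = 30
    max_mismatches: Optional[int] = 3
    allow_indels: bool = False
    require_proper_pair_if_paired: bool = True
    drop_duplicates: bool = True
    drop_qcfail: bool = True
    drop_secondary_supplementary: bool = True
    min_mapq: int = 1


# Rejection reason codes, in the order they are checked.
REASONS = (
    "unmapped",
    "secondary_supplementary",
    "multimapped",
    "duplicate",
    "qcfail",
    "unpaired",
    "indel",
    "mismatch",
    "length",
    "base_quality",
)

PASS = "pass"


def _count_mismatches(read: AlignedRead, genome) -> int:
    n = 0
    for qi, rpos in read.aligned_pairs():
        if read.seq[qi] != genome.base(read.chrom, rpos):
            n += 1
    return n


def assess_read(read: AlignedRead, params: QcParams, genome=None) -> str:
    """Classify one record: returns ``"pass"`` or a rejection reason code.

    Checks run in the documented fixed order; the first failing rule wins.
    When the mismatch count is unknown and a genome is supplied, it is
    recomputed from the aligned bases.
    """
    if read.is_unmapped:
        return "unmapped"
    if params.drop_secondary_supplementary and (read.is_secondary or read.is_supplementary):
        return "secondary_supplementary"
    if read.mapq < params.min_mapq:
        return "multimapped"
    if params.drop_duplicates and read.is_duplicate:
        return "duplicate"
    if params.drop_qcfail and read.is_qcfail:
        return "qcfail"
    if (
        params.require_proper_pair_if_paired
        and read.is_paired
        and not read.is_proper_pair
    ):
        return "unpaired"
    if not params.allow_indels and read.has_indel():
        return "indel"
    if params.max_mismatches is not None:
        nm = read.mismatch_count
        if nm is None and genome is not None:
            nm = _count_mismatches(read, genome)
        if nm is not None and nm > params.max_mismatches:
            return "mismatch"
    if read.query_length < params.min_read_len:
        return "length"
    if len(read.base_quals) and float(np.mean(read.base_quals)) < params.min_base_qual:
        return "base_quality"
    return PASS


def filter_alignments(
    reads: Iterable[AlignedRead], params: QcParams, genome=None
) -> tuple:
    """Apply :func:`assess_read` to a stream.

    Returns ``(passing, tally)`` where passing reads are unchanged except
    for the per-base quality mask, and ``tally`` is a Counter of rejection
    reasons; pass-count plus the tally total equals the input record count.
    """
    passing = []
    tally: Counter = Counter()
    for read in reads:
        verdict = assess_read(read, params, genome=genome)
        if verdict == PASS:
            quals = np.asarray(read.base_quals)
            read.mask = quals < params.min_base_qual
            passing.append(read)
        else:
            tally[verdict] += 1
    return passing, tally
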