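"""De novo variant calling restricted to junction-supporting split reads.

Each junction is divided into two independent parts at its splice sites:
the exonic anchor upstream of the intron (left, 5'ss side) and downstream
of it (right, 3'ss side).  Variants are called per part from a pileup of
only the supporting reads' anchor blocks, so a call is tied to one
junction side by construction.  Candidates must clear read-depth,
ALT-read-count and ALT-fraction floors and a one-sided Fisher test
against the sequencing-error expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .junctions import Junction, JunctionKey
from .readqc import AlignedRead
from .stats import fisher_greater, passes_alpha

BASES = "ACGT"


@dataclass
class VariantParams:
    min_depth: int = 3
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.1
    alpha_variant: float = 0.05
    error_rate: float = 0.001  # Q30 base-call error probability


@dataclass
class SidePileup:
    """Base counts over one anchor side of one junction.

    ``columns`` maps 0-based reference position to per-base counts from
    unmasked bases of supporting reads, restricted to the anchor block
    adjacent to the intron on that side.
    """

    junction: JunctionKey
    side: str  # "left" | "right"
    columns: Dict[int, Dict[str, int]] = field(default_factory=dict)

    @property
    def span(self) -> Optional[Tuple[int, int]]:
        """Inclusive (min, max) covered positions, or None if empty."""
        if not self.columns:
            return None
        return min(self.columns), max(self.columns)

    def depth(self, pos: int) -> int:
        col = self.columns.get(pos, {})
        return sum(col.get(b, 0) for b in BASES)


@dataclass
class VariantCandidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    junction: JunctionKey
    side: str
    depth: int
    alt_count: int
    p_variant: Optional[float] = None
    p_association: Optional[float] = None
    consistent: Optional[bool] = None
    used_universe: Optional[str] = None
    no_contrast: bool = False
    target_counts: Optional[Tuple[int, int]] = None  # (alt, ref) in target reads
    related_counts: Optional[Tuple[int, int]] = None  # (alt, ref) in related reads

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth


def anchor_block(read: AlignedRead, junction: JunctionKey, side: str) -> Optional[Tuple[int, int]]:
    """Reference span of the read's aligned block adjacent to the intron.

    For the left part this is the block ending exactly at the intron
    start; for the right part, the block starting at the intron end.
    Returns None when the read does not span this junction.
    """
    _, start, end = junction
    for bs, be in read.blocks():
        if side == "left" and be == start:
            return bs, be
        if side == "right" and bs == end:
            return bs, be
    return None


def build_side_pileup(
    junction: Junction,
    side: str,
    reads_by_id: Dict[str, AlignedRead],
    min_anchor: int = 0,
) -> SidePileup:
    """Pile up unmasked bases from the anchor blocks of supporting reads.

    Positions with zero unmasked coverage are omitted.  The pileup extent
    is the anchor block itself, not the whole read, keeping the two parts
    of the junction independent.
    """
    pile = SidePileup(junction.key, side)
    for rid in sorted(junction.supporting):
        read = reads_by_id.get(rid)
        if read is None:
            continue
        block = anchor_block(read, junction.key, side)
        if block is None or block[1] - block[0] < min_anchor:
            continue
        bs, be = block
        for qi, rpos in read.aligned_pairs():
            if not (bs <= rpos < be):
                continue
            if read.mask is not None and read.mask[qi]:
                continue
            base = read.seq[qi]
            if base not in BASES:
                continue
            col = pile.columns.setdefault(rpos, {})
            col[base] = col.get(base, 0) + 1
    return pile


def call_candidates(
    pileup: SidePileup, genome, params: VariantParams
) -> List[VariantCandidate]:
    """Form candidates from every non-reference base with support.

    A candidate is kept iff depth >= min_depth, ALT reads >= min_alt_reads
    and ALT fraction >= min_alt_fraction.  One column may yield several
    candidates with different ALT bases, each tested on its own counts.
    """
    chrom = pileup.junction[0]
    out: List[VariantCandidate] = []
    for pos in sorted(pileup.columns):
        col = pileup.columns[pos]
        depth = sum(col.get(b, 0) for b in BASES)
        if depth < params.min_depth:
            continue
        ref = genome.base(chrom, pos)
        for alt in BASES:
            if alt == ref:
                continue
            alt_count = col.get(alt, 0)
            if alt_count < params.min_alt_reads:
                continue
            if alt_count / depth < params.min_alt_fraction:
                continue
            out.append(
                VariantCandidate(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    junction=pileup.junction,
                    side=pileup.side,
                    depth=depth,
                    alt_count=alt_count,
                )
            )
    return out


def variant_significance(candidate: VariantCandidate, params: VariantParams) -> float:
    """One-sided Fisher p of the ALT count against the error expectation.

    The observed (alt, ref) split is compared with the split an error-only
    process would produce at the same depth, e = round(error_rate * depth)
    ALT calls.  Lowering error_rate can only lower the p-value.
    """
    e = round(params.error_rate * candidate.depth)
    return fisher_greater(
        candidate.alt_count,
        candidate.depth - candidate.alt_count,
        e,
        candidate.depth - e,
    )


def significant_candidates(
    candidates: List[VariantCandidate], params: VariantParams
) -> List[VariantCandidate]:
    """Score and keep candidates with p <= alpha_variant."""
    kept = []
    for c in candidates:
        c.p_variant = variant_significance(c, params)
        if passes_alpha(c.p_variant, params.alpha_variant):
            kept.append(c)
    return kept
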