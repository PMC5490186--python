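"""Variant-junction association testing and final record assembly.

For each candidate the ALT frequency in the target junction's reads is
first compared with the frequency in reads of related junctions (those
competing for the same splice site) by a two-sided Fisher test.  When the
frequencies are consistent, the association contrasts target-junction
reads against all other reads covering the site (related reads included);
when inconsistent, the combined target-plus-related reads form the
splicing-supporting row instead.  A one-sided Fisher test then asks
whether the ALT allele is enriched among splicing-supporting reads.  A
site with no non-supporting coverage at all is junction-private: it is
kept with p recorded as 0 and flagged "no-contrast".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

from intervaltree import IntervalTree

from .junctions import Junction, JunctionKey
from .readqc import AlignedRead
from .stats import fisher_greater, fisher_two_sided, passes_alpha
from .variants import BASES, VariantCandidate


@dataclass
class AssocParams:
    alpha_assoc: float = 0.05
    alpha_consistency: float = 0.05
    multiple_testing: str = "none"  # "none" | "BH"


class ReadIndex:
    """Spatial index of aligned blocks of passing reads, per chromosome."""

    def __init__(self, reads: Iterable[AlignedRead]):
        self.reads: Dict[str, AlignedRead] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for read in reads:
            self.reads[read.read_id] = read
            tree = self._trees.setdefault(read.chrom, IntervalTree())
            for bs, be in read.blocks():
                if be > bs:
                    tree.addi(bs, be, read.read_id)

    def covering(self, chrom: str, pos: int) -> Set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree[pos]}


def allele_counts(
    read_ids: Iterable[str],
    index: ReadIndex,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> Tuple[int, int]:
    """(alt, ref) base-call counts at pos among the given reads.

    Only unmasked calls equal to REF or ALT are counted; other bases (or
    reads without an aligned base there) contribute nothing.
    """
    n_alt = n_ref = 0
    for rid in read_ids:
        read = index.reads.get(rid)
        if read is None or read.chrom != chrom:
            continue
        hit = read.base_at(pos)
        if hit is None:
            continue
        base, _, qi = hit
        if read.mask is not None and read.mask[qi]:
            continue
        if base == alt:
            n_alt += 1
        elif base == ref:
            n_ref += 1
    return n_alt, n_ref


def consistency_check(
    target_counts: Tuple[int, int],
    related_counts: Tuple[int, int],
    params: AssocParams,
) -> bool:
    """ALT frequencies consistent between target and related junction reads?

    Consistent iff the two-sided Fisher p on [[alt_t, ref_t],
    [alt_r, ref_r]] exceeds alpha_consistency, or the related stratum has
    no coverage at the site.
    """
    alt_r, ref_r = related_counts
    if alt_r + ref_r == 0:
        return True
    alt_t, ref_t = target_counts
    return fisher_two_sided(alt_t, ref_t, alt_r, ref_r) > params.alpha_consistency


def association_test(
    row1: Tuple[int, int], row2: Tuple[int, int], params: AssocParams
) -> Tuple[float, bool]:
    """One-sided Fisher p for ALT enrichment in splicing-supporting reads.

    ``row1`` = (alt, ref) among splicing-supporting reads, ``row2`` among
    all other covering reads.  Returns (p, no_contrast): with zero
    coverage in row 2 the variant is fully junction-private and p is 0 by
    convention.
    """
    if row2[0] + row2[1] == 0:
        return 0.0, True
    p = fisher_greater(row1[0], row1[1], row2[0], row2[1])
    return p, False


def evaluate_candidate(
    cand: VariantCandidate,
    junction: Junction,
    related_junctions: List[Junction],
    index: ReadIndex,
    params: AssocParams,
) -> VariantCandidate:
    """Run the consistency branch and the association test for one candidate.

    Fills target/related counts, the consistency verdict, the read
    universe actually used and the association p-value in place.
    """
    target_ids = set(junction.supporting)
    related_ids: Set[str] = set()
    for rj in related_junctions:
        related_ids |= rj.supporting
    related_ids -= target_ids

    cand.target_counts = allele_counts(
        sorted(target_ids), index, cand.chrom, cand.pos, cand.ref, cand.alt
    )
    cand.related_counts = allele_counts(
        sorted(related_ids), index, cand.chrom, cand.pos, cand.ref, cand.alt
    )
    cand.consistent = consistency_check(
        cand.target_counts, cand.related_counts, params
    )

    covering = index.covering(cand.chrom, cand.pos)
    if cand.consistent:
        row1_ids = target_ids
        cand.used_universe = "target-only"
    else:
        row1_ids = target_ids | related_ids
        cand.used_universe = "related-total"
    row2_ids = covering - row1_ids

    if cand.consistent:
        row1 = cand.target_counts
    else:
        row1 = (
            cand.target_counts[0] + cand.related_counts[0],
            cand.target_counts[1] + cand.related_counts[1],
        )
    row2 = allele_counts(
        sorted(row2_ids), index, cand.chrom, cand.pos, cand.ref, cand.alt
    )
    cand.p_association, cand.no_contrast = association_test(row1, row2, params)
    return cand


def benjamini_hochberg(pvalues: List[float]) -> List[float]:
    """BH-adjusted p-values (monotone step-up)."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        running = min(running, pvalues[i] * n / rank)
        adj[i] = running
    return adj


@dataclass
class SvaseRecord:
    """A validated variant-junction association, ready for output."""

    chrom: str
    pos: int
    ref: str
    alt: str
    junction: JunctionKey
    side: str
    depth: int
    alt_count: int
    alt_fraction: float
    p_variant: float
    p_association: float
    consistent: bool
    used_universe: str
    no_contrast: bool
    junction_status: str
    background_p: float
    shift_of: Optional[JunctionKey] = None
    shift_offset: Optional[int] = None
    motif_class: Optional[str] = None
    strand: str = "."
    strand_confidence: str = "high"
    donor_ref: Optional[float] = None
    donor_alt: Optional[float] = None
    acceptor_ref: Optional[float] = None
    acceptor_alt: Optional[float] = None
    source_type: str = "novel"
    anchor_span: Optional[Tuple[int, int]] = None
    dist_breakpoint: Optional[int] = None
    dist_exon5: Optional[int] = None
    dist_exon3: Optional[int] = None
    subst_class: Optional[str] = None
    is_transition: Optional[bool] = None
    is_editing_pair: Optional[bool] = None


def assemble_records(
    candidates: List[VariantCandidate],
    junctions: Dict[JunctionKey, Junction],
    params: AssocParams,
) -> List[SvaseRecord]:
    """Apply the association cut (optionally BH-corrected) and build records.

    Records are sorted by (chrom, pos, junction key); a site shared by two
    junctions yields one record per junction key.
    """
    tested = [c for c in candidates if c.p_association is not None]
    if params.multiple_testing.upper() == "BH" and tested:
        adj = benjamini_hochberg([c.p_association for c in tested])
        cut = [c for c, pa in zip(tested, adj) if passes_alpha(pa, params.alpha_assoc)]
    else:
        cut = [c for c in tested if passes_alpha(c.p_association, params.alpha_assoc)]

    records = []
    for c in cut:
        j = junctions[c.junction]
        records.append(
            SvaseRecord(
                chrom=c.chrom,
                pos=c.pos,
                ref=c.ref,
                alt=c.alt,
                junction=c.junction,
                side=c.side,
                depth=c.depth,
                alt_count=c.alt_count,
                alt_fraction=c.alt_fraction,
                p_variant=c.p_variant,
                p_association=c.p_association,
                consistent=bool(c.consistent),
                used_universe=c.used_universe or "target-only",
                no_contrast=c.no_contrast,
                junction_status=j.status,
                background_p=j.background_p if j.background_p is not None else 0.0,
                shift_of=j.shift_of,
                shift_offset=j.shift_offset,
                motif_class=j.motif_class,
                strand=j.strand,
                strand_confidence=j.strand_confidence,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos, r.junction, r.alt))
    return records
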