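"""Splicing-event discovery and filtering from split reads.

A junction is the intron interval skipped by the ``N`` operation of a
split read, keyed ``(chrom, intron_start, intron_end)`` in 0-based
half-open coordinates.  Discovery enforces a minimum anchor (aligned
reference bases flanking the gap) on both sides; junctions are then
filtered by read depth and by a background-expression Fisher test against
their related junctions (those sharing the intron start or end), compared
with known annotation, and screened for small-offset alignment-ambiguity
("shift") artifacts of known junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .readqc import AlignedRead
from .stats import fisher_greater, passes_alpha

JunctionKey = Tuple[str, int, int]


@dataclass
class JunctionObservation:
    """One split-read crossing of one intron."""

    chrom: str
    intron_start: int
    intron_end: int
    left_anchor: int
    right_anchor: int
    read_id: str

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass
class Junction:
    chrom: str
    start: int
    end: int
    supporting: Set[str] = field(default_factory=set)
    status: str = "novel"  # known | novel | shift
    shift_of: Optional[JunctionKey] = None
    shift_offset: Optional[int] = None
    background_p: Optional[float] = None
    motif_class: Optional[str] = None
    strand: str = "."
    strand_confidence: str = "high"
    donor_score: Optional[float] = None
    acceptor_score: Optional[float] = None

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.start, self.end)

    @property
    def depth(self) -> int:
        return len(self.supporting)


@dataclass
class JunctionParams:
    min_anchor: int = 8
    min_junction_depth: int = 3
    background_rate: float = 0.01
    alpha_junction: float = 0.05
    max_shift: int = 10
    keep_known: bool = True


class MalformedAlignmentError(ValueError):
    pass


def junctions_from_read(read: AlignedRead, min_anchor: int = 8) -> List[JunctionObservation]:
    """Extract one observation per ``N`` CIGAR operation of a split read.

    Anchors are the aligned reference lengths of the blocks flanking that
    specific gap; for multi-gap reads the inter-intron block is the shared
    anchor of both neighbours.  Observations with either anchor below
    ``min_anchor`` are dropped.
    """
    # Partition the CIGAR into aligned-reference blocks separated by N ops;
    # within a block, M segments bridged by D merge (indel reads are normally
    # rejected upstream, but the walk stays total).
    blocks: List[List[int]] = []  # [ref_start, ref_end]
    gaps: List[Tuple[int, int]] = []  # (gap_start, gap_end)
    r = read.pos
    new_block = True
    for op, n in read.cigar:
        if op in "M=X":
            if new_block:
                blocks.append([r, r + n])
                new_block = False
            else:
                blocks[-1][1] = r + n
            r += n
        elif op == "D":
            r += n
        elif op == "N":
            if not blocks or new_block:
                raise MalformedAlignmentError(
                    f"read {read.read_id}: CIGAR gap without preceding aligned block"
                )
            gaps.append((r, r + n))
            r += n
            new_block = True
        # I, S, H, P consume no reference
    if gaps and new_block:
        raise MalformedAlignmentError(f"read {read.read_id}: CIGAR ends with N")

    out = []
    for i, (gs, ge) in enumerate(gaps):
        left = blocks[i][1] - blocks[i][0]
        right = blocks[i + 1][1] - blocks[i + 1][0]
        if left >= min_anchor and right >= min_anchor:
            out.append(
                JunctionObservation(read.chrom, gs, ge, left, right, read.read_id)
            )
    return out


def aggregate_junctions(
    observations: Iterable[JunctionObservation], params: JunctionParams
) -> Dict[JunctionKey, Junction]:
    """Group observations by intron interval and apply the depth filter.

    Depth counts distinct read IDs: a read observed twice for the same key
    still contributes one.  Junctions below ``min_junction_depth`` are
    discarded.
    """
    table: Dict[JunctionKey, Junction] = {}
    for obs in observations:
        j = table.get(obs.key)
        if j is None:
            j = Junction(obs.chrom, obs.intron_start, obs.intron_end)
            table[obs.key] = j
        j.supporting.add(obs.read_id)
    return {
        k: j for k, j in sorted(table.items()) if j.depth >= params.min_junction_depth
    }


def related_keys(
    junction: Junction, table: Dict[JunctionKey, Junction], side: Optional[str] = None
) -> Set[JunctionKey]:
    """Keys of junctions sharing a boundary with ``junction``.

    ``side=None`` returns the union (same start or same end) used by the
    junction-level background test.  For per-side variant work the
    competition for the LEFT part is among junctions sharing the intron
    END (alternative donors joined to one acceptor), and symmetrically the
    RIGHT part competes among junctions sharing the intron START.
    """
    chrom, start, end = junction.key
    out: Set[JunctionKey] = set()
    for key in table:
        if key == junction.key or key[0] != chrom:
            continue
        same_start = key[1] == start
        same_end = key[2] == end
        if side is None and (same_start or same_end):
            out.add(key)
        elif side == "left" and same_end:
            out.add(key)
        elif side == "right" and same_start:
            out.add(key)
    return out


def build_related_index(table: Dict[JunctionKey, Junction]) -> Dict[JunctionKey, dict]:
    """Precompute per-junction related sets (combined, left, right)."""
    by_start: Dict[Tuple[str, int], Set[JunctionKey]] = {}
    by_end: Dict[Tuple[str, int], Set[JunctionKey]] = {}
    for key in table:
        by_start.setdefault((key[0], key[1]), set()).add(key)
        by_end.setdefault((key[0], key[2]), set()).add(key)
    out = {}
    for key in table:
        same_start = by_start[(key[0], key[1])] - {key}
        same_end = by_end[(key[0], key[2])] - {key}
        out[key] = {
            "combined": same_start | same_end,
            "left": same_end,   # left part competes among shared-acceptor junctions
            "right": same_start,
        }
    return out


def background_test(
    junction: Junction, related: Iterable[Junction], params: JunctionParams
) -> float:
    """Background-expression significance of a junction among its relatives.

    With N the total depth over the junction and its related junctions and
    b = ceil(background_rate * N) the depth a pure-background junction
    would show, returns the one-sided (greater) Fisher exact p for
    [[depth, N - depth], [b, N - b]].  A junction with no relatives has no
    competition and is kept with p recorded as 0.
    """
    related = list(related)
    if not related:
        return 0.0
    n_total = junction.depth + sum(j.depth for j in related)
    b = math.ceil(params.background_rate * n_total)
    return fisher_greater(junction.depth, n_total - junction.depth, b, n_total - b)


def apply_background_filter(
    table: Dict[JunctionKey, Junction], params: JunctionParams
) -> Dict[JunctionKey, Junction]:
    """Score every junction and drop those not above background."""
    related_idx = build_related_index(table)
    kept: Dict[JunctionKey, Junction] = {}
    for key, j in table.items():
        rel = [table[k] for k in sorted(related_idx[key]["combined"])]
        j.background_p = background_test(j, rel, params)
        if passes_alpha(j.background_p, params.alpha_junction):
            kept[key] = j
    return kept


def classify_vs_known(
    table: Dict[JunctionKey, Junction], known, keep_known: bool = True
) -> Dict[JunctionKey, Junction]:
    """Mark junctions known/novel by exact intron-interval match.

    With ``keep_known=False`` known junctions are dropped from further
    analysis (novel-only mode).
    """
    out: Dict[JunctionKey, Junction] = {}
    for key, j in table.items():
        if known is not None and key in known:
            j.status = "known"
            if keep_known:
                out[key] = j
        else:
            j.status = "novel"
            out[key] = j
    return out


def detect_shift(
    junction: Junction, known, genome, max_shift: int = 10
) -> Optional[Tuple[JunctionKey, int]]:
    """Test whether a novel junction is an alignment-ambiguity shift of a
    known one.

    Searches offsets k = +1, -1, +2, -2, ... up to ``max_shift``: the
    novel intron must equal a known intron displaced by k, and the genome
    must make the two alignments equivalent — for k > 0 the k bases after
    the known intron start must repeat the k bases after its end
    (``genome[ks:ks+k] == genome[ke:ke+k]``), mirrored for k < 0.  Returns
    (known key, offset) for the smallest |k| (positive wins ties) or None.
    """
    chrom, s, e = junction.key
    seq = genome.sequences[chrom]
    for mag in range(1, max_shift + 1):
        for k in (mag, -mag):
            ks, ke = s - k, e - k
            if (chrom, ks, ke) not in known:
                continue
            if k > 0:
                if ke + k <= len(seq) and seq[ks : ks + k] == seq[ke : ke + k]:
                    return (chrom, ks, ke), k
            else:
                if ks + k >= 0 and seq[ks + k : ks] == seq[ke + k : ke]:
                    return (chrom, ks, ke), k
    return None


def apply_shift_detection(
    table: Dict[JunctionKey, Junction], known, genome, params: JunctionParams
) -> None:
    """Annotate novel junctions that shadow a known junction (in place)."""
    if known is None or len(known) == 0:
        return
    for j in table.values():
        if j.status != "novel":
            continue
        hit = detect_shift(j, known, genome, params.max_shift)
        if hit is not None:
            j.status = "shift"
            j.shift_of, j.shift_offset = hit
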