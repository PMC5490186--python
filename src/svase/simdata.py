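"""Deterministic synthetic data: genome, spliced reads and a truth table.

The generator emulates the situation the caller faces downstream of a
spliced aligner: a small multi-chromosome genome, junction-spanning reads
with configurable anchor lengths and per-junction depths, planted variant
alleles at configurable ALT fractions confined to (or shared across)
specific junctions, uniform base-call errors, non-split decoy reads and
optionally flagged records (duplicates, secondaries, QC failures).
Reads are emitted pre-"aligned" — the generator writes truthful SAM
directly, so the pipeline is tested, not an aligner.  Canonical GT-AG
motifs (or CT-AC for minus-strand junctions) are written into the genome
at every planted intron so strand inference is exercised.  The same seed
always produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .formats import GenomeIndex, revcomp, write_genome
from .readqc import AlignedRead
from .stats import fisher_greater, fisher_two_sided, passes_alpha

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark: one 1 Mb chromosome with
    200 unique GT-AG junctions at depth 30, 50 junction-private variants
    planted at ALT fraction 0.9, a Q30-like base error rate of 0.001 and
    10% non-split decoy reads.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 1_000_000
    n_junctions: int = 200
    intron_len: Tuple[int, int] = (80, 500)
    depth: Tuple[int, int] = (30, 30)
    anchor_len: Tuple[int, int] = (15, 40)
    n_variants: int = 50
    alt_fraction: float = 0.9
    placement: str = "junction-private"  # | shared-with-related | genome-wide
    error_rate: float = 0.001
    paired_end: bool = False
    decoy_fraction: float = 0.1
    minus_fraction: float = 0.0
    n_shared_pairs: int = 0
    n_genomewide_cover: int = 20  # dedicated decoys per genome-wide plant
    inject_duplicates: int = 0
    inject_secondary: int = 0
    inject_lowqual: int = 0
    inject_short: int = 0


@dataclass
class SimRead:
    read_id: str
    chrom: str
    pos: int
    cigar: Tuple[Tuple[str, int], ...]
    seq: List[str]
    flag: int = 0
    quals: Optional[List[int]] = None
    nm: int = 0

    def blocks(self) -> List[Tuple[int, int, int]]:
        """(ref_start, ref_end, query_start) per aligned block."""
        out, q, r = [], 0, self.pos
        for op, n in self.cigar:
            if op == "M":
                out.append((r, r + n, q))
                q += n
                r += n
            elif op == "N":
                r += n
        return out

    def qindex(self, rpos: int) -> Optional[int]:
        for rs, re_, qs in self.blocks():
            if rs <= rpos < re_:
                return qs + (rpos - rs)
        return None


@dataclass
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    junction: Tuple[str, int, int]
    side: str
    placement: str
    alt_fraction: float
    depth_target: int = 0
    alt_target: int = 0
    expected: bool = False


@dataclass
class TruthTable:
    junctions: List[Tuple[Tuple[str, int, int], int]] = field(default_factory=list)
    variants: List[PlantedVariant] = field(default_factory=list)

    @property
    def expected_set(self) -> set:
        return {
            (v.chrom, v.pos, v.ref, v.alt, v.junction)
            for v in self.variants
            if v.expected
        }


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeIndex
    reads: List[SimRead]
    truth: TruthTable


@dataclass
class _JSpec:
    chrom: str
    start: int
    end: int
    strand: str
    index: int
    pair_with: Optional[int] = None


def _place_junctions(cfg: SimConfig, rng, arrays) -> List[_JSpec]:
    chroms = sorted(arrays)
    margin, pad, spacing = 100, 10, 50
    max_anchor = cfg.anchor_len[1]
    cursors = {c: margin for c in chroms}
    specs: List[_JSpec] = []
    n_paired = 2 * cfg.n_shared_pairs
    if n_paired > cfg.n_junctions:
        raise ValueError("n_shared_pairs exceeds n_junctions")
    i = 0
    ci = 0
    while i < cfg.n_junctions:
        chrom = chroms[ci % len(chroms)]
        ci += 1
        ilen = int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        strand = "-" if rng.random() < cfg.minus_fraction else "+"
        paired = i < n_paired  # pairs are laid out two at a time
        extra = 60 if paired else 0
        s = cursors[chrom] + max_anchor + pad + extra
        e = s + ilen
        cursors[chrom] = e + max_anchor + pad + spacing
        if cursors[chrom] > cfg.chrom_len - margin:
            raise ValueError(
                "infeasible config: junctions do not fit on the chromosomes"
            )
        specs.append(_JSpec(chrom, s, e, strand, i))
        i += 1
        if paired:
            # partner shares the intron end, starts 60 bp earlier
            specs.append(_JSpec(chrom, s - 60, e, strand, i, pair_with=i - 1))
            specs[-2].pair_with = i
            i += 1
    for sp in specs:
        arr = arrays[sp.chrom]
        if sp.strand == "+":
            arr[sp.start : sp.start + 2] = np.frombuffer(b"GT", dtype="S1")
            arr[sp.end - 2 : sp.end] = np.frombuffer(b"AG", dtype="S1")
        else:
            arr[sp.start : sp.start + 2] = np.frombuffer(b"CT", dtype="S1")
            arr[sp.end - 2 : sp.end] = np.frombuffer(b"AC", dtype="S1")
    return specs


def simulate(cfg: SimConfig) -> SimResult:
    """Generate genome, reads and truth table for one configuration."""
    rng = np.random.default_rng(cfg.seed)
    arrays = {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, cfg.chrom_len)].copy()
        for i in range(cfg.n_chroms)
    }
    specs = _place_junctions(cfg, rng, arrays)
    genome = GenomeIndex(
        {c: arrays[c].tobytes().decode() for c in sorted(arrays)}
    )

    base_flag = 0x1 | 0x2 | 0x40 if cfg.paired_end else 0

    # --- junction-spanning reads ---
    reads_by_junction: Dict[int, List[SimRead]] = {}
    all_reads: List[SimRead] = []
    for sp in specs:
        d = int(rng.integers(cfg.depth[0], cfg.depth[1] + 1))
        jreads = []
        for k in range(d):
            la = int(rng.integers(cfg.anchor_len[0], cfg.anchor_len[1] + 1))
            ra = int(rng.integers(cfg.anchor_len[0], cfg.anchor_len[1] + 1))
            pos = sp.start - la
            seq = list(
                genome.sequences[sp.chrom][pos : sp.start]
                + genome.sequences[sp.chrom][sp.end : sp.end + ra]
            )
            r = SimRead(
                read_id=f"j{sp.index}_r{k}",
                chrom=sp.chrom,
                pos=pos,
                cigar=(("M", la), ("N", sp.end - sp.start), ("M", ra)),
                seq=seq,
                flag=base_flag,
            )
            jreads.append(r)
            all_reads.append(r)
        reads_by_junction[sp.index] = jreads

    # --- non-split decoy reads ---
    n_decoys = round(cfg.decoy_fraction * len(all_reads))
    rlen = 50
    for k in range(n_decoys):
        chrom = sorted(arrays)[int(rng.integers(0, cfg.n_chroms))]
        pos = int(rng.integers(0, cfg.chrom_len - rlen))
        all_reads.append(
            SimRead(
                read_id=f"d{k}",
                chrom=chrom,
                pos=pos,
                cigar=(("M", rlen),),
                seq=list(genome.sequences[chrom][pos : pos + rlen]),
                flag=base_flag,
            )
        )

    # --- plant variants ---
    truth = TruthTable(
        junctions=[
            ((sp.chrom, sp.start, sp.end), len(reads_by_junction[sp.index]))
            for sp in specs
        ]
    )
    if cfg.placement == "shared-with-related":
        eligible = [sp.index for sp in specs if sp.pair_with is not None]
        eligible = eligible[::2]  # one plant per pair
    else:
        eligible = [sp.index for sp in specs if sp.pair_with is None]
    if cfg.n_variants > len(eligible):
        raise ValueError("more planted variants than eligible junctions")
    chosen = rng.choice(np.array(eligible), size=cfg.n_variants, replace=False)

    plants: List[PlantedVariant] = []
    for ji in sorted(int(x) for x in chosen):
        sp = specs[ji]
        side = "left" if rng.random() < 0.5 else "right"
        off = int(rng.integers(3, 9))
        pos = sp.start - off if side == "left" else sp.end + off - 1
        ref = genome.sequences[sp.chrom][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))

        targets = list(reads_by_junction[ji])
        extra_groups: List[List[SimRead]] = []
        if cfg.placement == "shared-with-related" and sp.pair_with is not None:
            extra_groups.append(list(reads_by_junction[sp.pair_with]))
        if cfg.placement == "genome-wide":
            dedicated = []
            for k in range(cfg.n_genomewide_cover):
                start = max(0, pos - int(rng.integers(5, rlen - 5)))
                dedicated.append(
                    SimRead(
                        read_id=f"g{ji}_{k}",
                        chrom=sp.chrom,
                        pos=start,
                        cigar=(("M", rlen),),
                        seq=list(genome.sequences[sp.chrom][start : start + rlen]),
                        flag=base_flag,
                    )
                )
            all_reads.extend(dedicated)
            extra_groups.append(dedicated)

        for group in [targets] + extra_groups:
            covering = [r for r in group if r.qindex(pos) is not None]
            n_alt = round(cfg.alt_fraction * len(covering))
            picked = rng.permutation(len(covering))[:n_alt]
            for idx in picked:
                r = covering[int(idx)]
                r.seq[r.qindex(pos)] = alt

        plants.append(
            PlantedVariant(
                chrom=sp.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                junction=(sp.chrom, sp.start, sp.end),
                side=side,
                placement=cfg.placement,
                alt_fraction=cfg.alt_fraction,
            )
        )

    # --- sequencing errors ---
    if cfg.error_rate > 0:
        for r in all_reads:
            hits = np.flatnonzero(rng.random(len(r.seq)) < cfg.error_rate)
            for qi in hits:
                cur = r.seq[int(qi)]
                r.seq[int(qi)] = str(rng.choice([b for b in "ACGT" if b != cur]))

    # --- flagged extras ---
    extras: List[SimRead] = []
    for k in range(cfg.inject_duplicates):
        src = all_reads[k % len(all_reads)]
        extras.append(replace(src, read_id=src.read_id + "_dup", seq=list(src.seq),
                              flag=src.flag | 0x400))
    for k in range(cfg.inject_secondary):
        src = all_reads[k % len(all_reads)]
        extras.append(replace(src, read_id=src.read_id + "_sec", seq=list(src.seq),
                              flag=src.flag | 0x100))
    for k in range(cfg.inject_lowqual):
        src = all_reads[k % len(all_reads)]
        extras.append(replace(src, read_id=src.read_id + "_lq", seq=list(src.seq),
                              quals=[20] * len(src.seq)))
    for k in range(cfg.inject_short):
        chrom = sorted(arrays)[0]
        pos = 200 + 30 * k
        extras.append(
            SimRead(
                read_id=f"short{k}",
                chrom=chrom,
                pos=pos,
                cigar=(("M", 20),),
                seq=list(genome.sequences[chrom][pos : pos + 20]),
                flag=base_flag,
            )
        )
    all_reads.extend(extras)

    # --- finalize: qualities and mismatch tags ---
    for r in all_reads:
        if r.quals is None:
            r.quals = [40] * len(r.seq)
        r.nm = _mismatches(r, genome)

    truth.variants = plants
    _fill_expected(truth, all_reads, specs, reads_by_junction)
    all_reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    return SimResult(cfg, genome, all_reads, truth)


def _mismatches(read: SimRead, genome: GenomeIndex) -> int:
    n = 0
    seq = genome.sequences[read.chrom]
    for rs, re_, qs in read.blocks():
        for i in range(re_ - rs):
            if read.seq[qs + i] != seq[rs + i]:
                n += 1
    return n


def _allele_counts(reads, pos, ref, alt) -> Tuple[int, int]:
    n_alt = n_ref = 0
    for r in reads:
        qi = r.qindex(pos)
        if qi is None:
            continue
        b = r.seq[qi]
        if b == alt:
            n_alt += 1
        elif b == ref:
            n_ref += 1
    return n_alt, n_ref


def _fill_expected(truth, all_reads, specs, reads_by_junction) -> None:
    """Decide, from the generated reads and the documented default
    thresholds, which plants the pipeline must emit."""
    spec_by_key = {(sp.chrom, sp.start, sp.end): sp for sp in specs}
    target_ids = {
        (sp.chrom, sp.start, sp.end): {r.read_id for r in reads_by_junction[sp.index]}
        for sp in specs
    }
    for v in truth.variants:
        sp = spec_by_key[v.junction]
        tids = target_ids[v.junction]
        tgt = [r for r in all_reads if r.read_id in tids]
        related: List[SimRead] = []
        if sp.pair_with is not None:
            rids = {r.read_id for r in reads_by_junction[sp.pair_with]}
            related = [r for r in all_reads if r.read_id in rids]
        rel_ids = {r.read_id for r in related}
        others = [
            r
            for r in all_reads
            if r.chrom == v.chrom
            and r.read_id not in tids
            and r.read_id not in rel_ids
            # flagged extras and low-quality injections never pass QC
            and not (r.flag & (0x100 | 0x200 | 0x400 | 0x800))
            and (r.quals is None or sum(r.quals) / len(r.quals) >= 30)
        ]

        alt_t, ref_t = _allele_counts(tgt, v.pos, v.ref, v.alt)
        alt_r, ref_r = _allele_counts(related, v.pos, v.ref, v.alt)
        alt_o, ref_o = _allele_counts(others, v.pos, v.ref, v.alt)
        depth = sum(1 for r in tgt if r.qindex(v.pos) is not None)
        v.depth_target, v.alt_target = depth, alt_t

        ok = depth >= 3 and alt_t >= 3 and alt_t / depth >= 0.1
        if ok:
            e = round(0.001 * depth)
            ok = passes_alpha(fisher_greater(alt_t, depth - alt_t, e, depth - e), 0.05)
        if ok:
            consistent = (
                alt_r + ref_r == 0
                or fisher_two_sided(alt_t, ref_t, alt_r, ref_r) > 0.05
            )
            if consistent:
                row1, row2 = (alt_t, ref_t), (alt_o + alt_r, ref_o + ref_r)
            else:
                row1, row2 = (alt_t + alt_r, ref_t + ref_r), (alt_o, ref_o)
            if row2[0] + row2[1] > 0:
                ok = passes_alpha(fisher_greater(*row1, *row2), 0.05)
        v.expected = bool(ok)


# ----------------------------------------------------------------------
# Conversions and file output
# ----------------------------------------------------------------------

def to_aligned_reads(sim: SimResult) -> List[AlignedRead]:
    """In-memory bridge from simulated reads to pipeline input records."""
    return [
        AlignedRead(
            read_id=r.read_id,
            chrom=r.chrom,
            pos=r.pos,
            cigar=r.cigar,
            seq="".join(r.seq),
            base_quals=tuple(r.quals),
            mapq=60,
            flag=r.flag,
            mismatch_count=r.nm,
        )
        for r in sim.reads
    ]


def write_sam(sim: SimResult, path) -> None:
    """Write the simulated reads as coordinate-sorted SAM."""
    chroms = sorted(sim.genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(sim.genome.sequences[c])} for c in chroms],
    }
    cid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sim.reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = r.flag
            a.reference_id = cid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            a.query_sequence = "".join(r.seq)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.set_tag("NM", r.nm, "i")
            out.write(a)


def write_truth(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#type\tchrom\tpos\tref\talt\tjunction\tside\tplacement"
                 "\talt_fraction\tdepth_target\talt_target\texpected\n")
        for key, depth in truth.junctions:
            fh.write(f"junction\t{key[0]}\t{key[1]}\t.\t.\t{key[0]}:{key[1]}-{key[2]}"
                     f"\t.\t.\t.\t{depth}\t.\t.\n")
        for v in truth.variants:
            fh.write(
                f"variant\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
                f"\t{v.junction[0]}:{v.junction[1]}-{v.junction[2]}\t{v.side}"
                f"\t{v.placement}\t{v.alt_fraction}\t{v.depth_target}"
                f"\t{v.alt_target}\t{int(v.expected)}\n"
            )


def simulate_to_dir(cfg: SimConfig, out_dir) -> SimResult:
    """Run the generator and write genome.fa, reads.sam and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate(cfg)
    write_genome(sim.genome, out / "genome.fa")
    write_sam(sim, out / "reads.sam")
    write_truth(sim.truth, out / "truth.tsv")
    return sim


# ----------------------------------------------------------------------
# Dataset transformations for invariance tests
# ----------------------------------------------------------------------

def mirror_dataset(sim: SimResult) -> SimResult:
    """Reverse-complement the genome and mirror every read.

    A junction [s, e) on a contig of length L maps to [L-e, L-s); reads
    map to the opposite strand with reversed CIGARs.  The transformation
    is an involution, so any strand-symmetric caller must produce the
    mirrored result set with identical statistics.
    """
    lengths = sim.genome.lengths
    genome = GenomeIndex(
        {c: revcomp(s) for c, s in sim.genome.sequences.items()}
    )
    reads = []
    for r in sim.reads:
        L = lengths[r.chrom]
        ref_len = sum(n for op, n in r.cigar if op in "MN")
        reads.append(
            SimRead(
                read_id=r.read_id,
                chrom=r.chrom,
                pos=L - (r.pos + ref_len),
                cigar=tuple(reversed(r.cigar)),
                seq=list(revcomp("".join(r.seq))),
                flag=r.flag ^ 0x10,
                quals=list(reversed(r.quals)),
                nm=r.nm,
            )
        )
    reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    comp = str.maketrans("ACGT", "TGCA")
    variants = [
        replace(
            v,
            pos=lengths[v.chrom] - 1 - v.pos,
            ref=v.ref.translate(comp),
            alt=v.alt.translate(comp),
            junction=(v.junction[0],
                      lengths[v.chrom] - v.junction[2],
                      lengths[v.chrom] - v.junction[1]),
            side={"left": "right", "right": "left"}[v.side],
        )
        for v in sim.truth.variants
    ]
    truth = TruthTable(
        junctions=[
            ((k[0], lengths[k[0]] - k[2], lengths[k[0]] - k[1]), d)
            for k, d in sim.truth.junctions
        ],
        variants=variants,
    )
    return SimResult(sim.config, genome, reads, truth)


def make_shift_fixture(
    n_known: int = 20,
    offsets: Optional[List[int]] = None,
    break_repeats: bool = False,
    seed: int = 0,
):
    """Known introns each shadowed by a boundary-repeat shifted novel twin.

    For each known intron [s, e) and offset k, the k bases following the
    intron start are copied to follow the intron end (mirrored for
    negative k), making the alignment of the shifted novel intron
    [s+k, e+k) genuinely ambiguous.  With ``break_repeats`` the repeat is
    deliberately destroyed, so no shift should be detected.  Returns
    (genome, known_set, [(novel_key, expected_offset), ...]).
    """
    from .formats import KnownJunctionSet

    if offsets is None:
        offsets = [1, 2, 3, -1, -2, -3]
    rng = np.random.default_rng(seed)
    chrom_len = 600 * (n_known + 1)
    arr = _BASES[rng.integers(0, 4, chrom_len)].copy()
    known = KnownJunctionSet(source_format="BED")
    novels = []
    for i in range(n_known):
        k = offsets[i % len(offsets)]
        s = 600 * i + 200
        e = s + 100 + 7 * i  # distinct intron lengths
        arr[s : s + 2] = np.frombuffer(b"GT", dtype="S1")
        arr[e - 2 : e] = np.frombuffer(b"AG", dtype="S1")
        if k > 0:
            src, dst = arr[s : s + k].copy(), slice(e, e + k)
        else:
            src, dst = arr[s + k : s].copy(), slice(e + k, e)
        if break_repeats:
            broken = src.copy()
            for j in range(len(broken)):
                cur = broken[j]
                broken[j] = next(b for b in _BASES if b != cur)
            arr[dst] = broken
        else:
            arr[dst] = src
        known.junctions.add(("chr1", s, e, "+"))
        novels.append((("chr1", s + k, e + k), k))
    genome = GenomeIndex({"chr1": arr.tobytes().decode()})
    return genome, known, novels


# ----------------------------------------------------------------------
# Evaluation against truth
# ----------------------------------------------------------------------

def evaluate(records, truth: TruthTable, records_b=None) -> dict:
    """Precision/recall of emitted records against the truth table.

    A match is exact on (chrom, pos, ref, alt, junction key).  With a
    second record set, per-run replicate consistency (shared records over
    each run's total) is also reported.
    """
    def keyset(recs):
        return {(r.chrom, r.pos, r.ref, r.alt, r.junction) for r in recs}

    emitted = keyset(records)
    expected = truth.expected_set
    matched = emitted & expected
    out = {
        "n_emitted": len(emitted),
        "n_expected": len(expected),
        "n_matched": len(matched),
        "precision": len(matched) / len(emitted) if emitted else float("nan"),
        "recall": len(matched) / len(expected) if expected else float("nan"),
    }
    if records_b is not None:
        other = keyset(records_b)
        common = emitted & other
        out["consistency_a"] = len(common) / len(emitted) if emitted else float("nan")
        out["consistency_b"] = len(common) / len(other) if other else float("nan")
    return out
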