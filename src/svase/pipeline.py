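"""End-to-end orchestration: QC, junctions, variants, association, output.

The stage order is fixed: read QC -> junction discovery -> depth and
background filters -> known/novel classification and shift detection ->
per-side variant calling -> variant significance -> consistency ->
association -> splice-signal scoring -> source annotation -> summary
tables.  There is no sampling anywhere on this path and all set
iterations are ordered, so a given input and configuration always
produce identical output; chromosomes are processed independently and
results merged in sorted order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import assoc as assoc_mod
from . import formats, junctions as junc_mod, readqc, report, splicesignal, variants as var_mod
from .assoc import AssocParams, ReadIndex, SvaseRecord
from .formats import GenomeIndex, KnownJunctionSet, KnownSiteIndex
from .junctions import Junction, JunctionParams
from .readqc import AlignedRead, QcParams
from .stats import passes_alpha
from .variants import VariantParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults match the per-module defaults."""

    genome: str = ""
    alignments: str = ""
    out_dir: str = "svase_out"
    known_junctions: Optional[str] = None
    known_junction_format: Optional[str] = None
    dna_sites: Optional[str] = None
    editing_sites: Optional[str] = None
    keep_known: bool = True
    qc: QcParams = field(default_factory=QcParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    variant: VariantParams = field(default_factory=VariantParams)
    assoc: AssocParams = field(default_factory=AssocParams)
    flank_bp: int = 50
    pseudocount: float = 0.25
    signal_model: Optional[str] = None
    write_plots: bool = False
    threads: int = 1
    log_level: str = "INFO"
    seed: int = 0


def validate_config(config: RunConfig) -> List[str]:
    """Return a list of problems; empty iff every invariant holds."""
    problems = []
    if not config.genome:
        problems.append("genome: path is required")
    elif not Path(config.genome).exists():
        problems.append(f"genome: file not found: {config.genome}")
    if not config.alignments:
        problems.append("alignments: path is required")
    elif not Path(config.alignments).exists():
        problems.append(f"alignments: file not found: {config.alignments}")
    for name, val in (
        ("qc.min_base_qual", config.qc.min_base_qual),
        ("qc.min_read_len", config.qc.min_read_len),
        ("junction.min_anchor", config.junction.min_anchor),
        ("junction.min_junction_depth", config.junction.min_junction_depth),
        ("variant.min_depth", config.variant.min_depth),
        ("variant.min_alt_reads", config.variant.min_alt_reads),
        ("flank_bp", config.flank_bp),
    ):
        if val < 1:
            problems.append(f"{name}: must be >= 1 (got {val})")
    for name, val in (
        ("junction.background_rate", config.junction.background_rate),
        ("variant.min_alt_fraction", config.variant.min_alt_fraction),
    ):
        if not 0 < val < 1:
            problems.append(f"{name}: must be in (0, 1) (got {val})")
    for name, val in (
        ("junction.alpha_junction", config.junction.alpha_junction),
        ("variant.alpha_variant", config.variant.alpha_variant),
        ("assoc.alpha_assoc", config.assoc.alpha_assoc),
        ("assoc.alpha_consistency", config.assoc.alpha_consistency),
    ):
        if not 0 < val < 1:
            problems.append(f"{name}: must be in (0, 1) (got {val})")
    if not 0 <= config.variant.error_rate < 1:
        problems.append("variant.error_rate: must be in [0, 1)")
    if config.assoc.multiple_testing.upper() not in ("NONE", "BH"):
        problems.append("assoc.multiple_testing: must be 'none' or 'BH'")
    return problems


@dataclass
class PipelineResult:
    records: List[SvaseRecord]
    junctions: Dict
    qc_tally: Dict[str, int]
    stage_counts: Dict[str, int]
    rejected: List  # candidates that failed consistency/association
    model: Optional[splicesignal.SpliceSignalModel] = None


def call_svase(
    genome: GenomeIndex,
    reads,
    known_junctions: Optional[KnownJunctionSet] = None,
    dna_sites: Optional[KnownSiteIndex] = None,
    editing_sites: Optional[KnownSiteIndex] = None,
    qc: Optional[QcParams] = None,
    jparams: Optional[JunctionParams] = None,
    vparams: Optional[VariantParams] = None,
    aparams: Optional[AssocParams] = None,
    pseudocount: float = 0.25,
    signal_model: Optional[splicesignal.SpliceSignalModel] = None,
) -> PipelineResult:
    """Run the whole caller in memory and return records plus diagnostics."""
    qc = qc or QcParams()
    jparams = jparams or JunctionParams()
    vparams = vparams or VariantParams()
    aparams = aparams or AssocParams()
    counts: Dict[str, int] = {}

    # 1. read QC
    passing, tally = readqc.filter_alignments(reads, qc, genome=genome)
    counts["reads_in"] = len(passing) + sum(tally.values())
    counts["reads_pass"] = len(passing)

    # 2. junction discovery with anchor rule
    observations = []
    for read in passing:
        if read.has_gap():
            observations.extend(junc_mod.junctions_from_read(read, jparams.min_anchor))
    counts["junction_observations"] = len(observations)

    # 3. depth filter
    table = junc_mod.aggregate_junctions(observations, jparams)
    counts["junctions_depth_pass"] = len(table)

    # 4. background-expression filter
    table = junc_mod.apply_background_filter(table, jparams)
    counts["junctions_background_pass"] = len(table)

    # 5. known/novel classification and shift detection
    table = junc_mod.classify_vs_known(table, known_junctions, jparams.keep_known)
    junc_mod.apply_shift_detection(table, known_junctions, genome, jparams)
    counts["junctions_final"] = len(table)

    # 6. splice-signal model and junction annotation
    for j in table.values():
        j.motif_class, j.strand = splicesignal.motif_and_strand(j.key, genome)
    if signal_model is None:
        if known_junctions is not None and len(known_junctions):
            signal_model = splicesignal.train_from_known(
                known_junctions, genome, pseudocount
            )
        else:
            pairs = [
                (j.key, j.strand) for j in table.values() if j.strand in "+-"
            ]
            signal_model = (
                splicesignal.train_model(sorted(pairs), genome, pseudocount)
                if pairs
                else splicesignal.uniform_model(pseudocount)
            )
    for j in table.values():
        d, a, st, conf = splicesignal.score_junction(j.key, j.strand, signal_model, genome)
        j.donor_score, j.acceptor_score = d, a
        if j.strand == ".":
            j.strand, j.strand_confidence = st, conf

    # 7. per-side variant calling
    reads_by_id = {r.read_id: r for r in passing}
    pileups: Dict = {}
    candidates: List = []
    for key in sorted(table):
        j = table[key]
        for side in ("left", "right"):
            pile = var_mod.build_side_pileup(j, side, reads_by_id)
            pileups[(key, side)] = pile
            candidates.extend(var_mod.call_candidates(pile, genome, vparams))
    counts["variant_candidates"] = len(candidates)

    # 8. variant significance
    candidates = var_mod.significant_candidates(candidates, vparams)
    counts["variants_significant"] = len(candidates)

    # 9. consistency + association
    index = ReadIndex(passing)
    related_idx = junc_mod.build_related_index(table)
    for cand in candidates:
        rel_keys = sorted(related_idx[cand.junction][cand.side])
        assoc_mod.evaluate_candidate(
            cand, table[cand.junction], [table[k] for k in rel_keys], index, aparams
        )
    records = assoc_mod.assemble_records(candidates, table, aparams)
    rejected = [c for c in candidates if c.p_association is not None
                and not passes_alpha(c.p_association, aparams.alpha_assoc)]
    counts["svase_records"] = len(records)

    # 10. signal scoring, distances, source annotation
    for r in records:
        splicesignal.score_ref_vs_alt(r, signal_model, genome)
        pile = pileups.get((r.junction, r.side))
        r.anchor_span = pile.span if pile is not None else None
        j = table[r.junction]
        r.dist_breakpoint, r.dist_exon5, r.dist_exon3 = report.breakpoint_distances(r, j)
        r.subst_class, r.is_transition, r.is_editing_pair = report.substitution_class(
            r.ref, r.alt
        )
        r.source_type = report.annotate_source(r, dna_sites, editing_sites)

    result = PipelineResult(
        records=records,
        junctions=table,
        qc_tally=dict(tally),
        stage_counts=counts,
        rejected=rejected,
        model=signal_model,
    )
    audit_result(result, jparams, vparams, aparams, reads_by_id)
    return result


def audit_result(
    result: PipelineResult,
    jparams: JunctionParams,
    vparams: VariantParams,
    aparams: AssocParams,
    reads_by_id: Optional[Dict[str, AlignedRead]] = None,
) -> int:
    """Post-run assertion suite: every emitted record satisfies every gate.

    Checks count floors (depth, ALT reads, ALT fraction), all three
    significance gates, read length, and — when reads are available —
    the anchor rule on every supporting observation.  Raises
    AssertionError on the first violation; returns the number of records
    audited.
    """
    for r in result.records:
        assert r.depth >= vparams.min_depth, f"depth gate violated: {r}"
        assert r.alt_count >= vparams.min_alt_reads, f"ALT count gate violated: {r}"
        assert r.alt_fraction >= vparams.min_alt_fraction, f"ALT fraction gate: {r}"
        assert passes_alpha(r.p_variant, vparams.alpha_variant), f"variant significance gate: {r}"
        assert passes_alpha(r.p_association, aparams.alpha_assoc), f"association gate: {r}"
        assert passes_alpha(r.background_p, jparams.alpha_junction), f"background gate: {r}"
        j = result.junctions[r.junction]
        assert j.depth >= jparams.min_junction_depth, f"junction depth gate: {r}"
        if reads_by_id is not None:
            for rid in j.supporting:
                read = reads_by_id[rid]
                assert read.query_length >= 30, f"short supporting read {rid}"
                for obs in junc_mod.junctions_from_read(read, 1):
                    if obs.key == r.junction:
                        assert (
                            obs.left_anchor >= jparams.min_anchor
                            and obs.right_anchor >= jparams.min_anchor
                        ), f"anchor rule violated by {rid} at {r.junction}"
    return len(result.records)


def run(config: RunConfig) -> PipelineResult:
    """File-based entry point: load inputs, call, write all outputs."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = formats.load_genome(config.genome)
    reads = formats.read_alignments(config.alignments, genome)
    known = (
        formats.load_known_junctions(config.known_junctions, config.known_junction_format)
        if config.known_junctions
        else None
    )
    dna = (
        formats.load_known_sites(config.dna_sites, label="DNA mutation")
        if config.dna_sites
        else None
    )
    edit = (
        formats.load_known_sites(config.editing_sites, label="RNA editing")
        if config.editing_sites
        else None
    )
    model = (
        splicesignal.load_model(config.signal_model) if config.signal_model else None
    )
    jparams = config.junction
    jparams.keep_known = config.keep_known

    result = call_svase(
        genome,
        reads,
        known_junctions=known,
        dna_sites=dna,
        editing_sites=edit,
        qc=config.qc,
        jparams=jparams,
        vparams=config.variant,
        aparams=config.assoc,
        pseudocount=config.pseudocount,
        signal_model=model,
    )

    write_outputs(result, genome, config)
    return result


def records_frame(records: List[SvaseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["pos"] = r.pos + 1  # report 1-based
        d["junction"] = f"{r.junction[0]}:{r.junction[1]}-{r.junction[2]}"
        d["shift_of"] = (
            f"{r.shift_of[0]}:{r.shift_of[1]}-{r.shift_of[2]}" if r.shift_of else ""
        )
        d["anchor_span"] = (
            f"{r.anchor_span[0]}-{r.anchor_span[1]}" if r.anchor_span else ""
        )
        rows.append(d)
    cols = [f.name for f in SvaseRecord.__dataclass_fields__.values()] if rows else []
    return pd.DataFrame(rows, columns=cols or None)


def write_outputs(result: PipelineResult, genome: GenomeIndex, config: RunConfig) -> None:
    out = Path(config.out_dir)
    records_frame(result.records).to_csv(out / "svase.tsv", sep="\t", index=False)
    formats.write_vcf(result.records, genome, out / "svase.vcf")
    formats.write_flank_fasta(
        result.records, genome, out / "flanks.fa", flank_bp=config.flank_bp
    )
    formats.write_junction_bed(
        [result.junctions[k] for k in sorted(result.junctions)], out / "junctions.bed"
    )
    pd.DataFrame(
        [{"reason": k, "count": v} for k, v in sorted(result.qc_tally.items())]
        + [{"reason": "pass", "count": result.stage_counts["reads_pass"]}]
    ).to_csv(out / "qc_tally.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"stage": k, "count": v} for k, v in result.stage_counts.items()]
    ).to_csv(out / "stage_counts.tsv", sep="\t", index=False)
    report.summarize(result.records, result.junctions, out_dir=out / "summary")
    if result.model is not None:
        splicesignal.save_model(result.model, out / "signal_model.txt")
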