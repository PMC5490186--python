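"""Source-type annotation and descriptive summary tables.

Once records are validated, each variant is labelled against optional
known DNA-mutation and RNA-editing site lists, classified into the six
strand-symmetric substitution pairs (A>G/T>C is the A-to-I editing
signature), and measured against its junction: distance to the intron
breakpoint and to the two ends of the anchor-covered exon segment.  The
summaries mirror the standard characterisation of splice-associated
variants: junction depth and splice-motif distributions, reference vs
variant splice-signal scores, distance histograms and the substitution
spectrum, each produced for all junctions and for novel junctions only.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .assoc import SvaseRecord
from .formats import KnownSiteIndex
from .junctions import Junction

PURINES = {"A", "G"}

# 12 directed substitutions collapsed into 6 strand-symmetric pairs
_PAIR = {
    ("A", "G"): "A>G/T>C", ("T", "C"): "A>G/T>C",
    ("G", "A"): "G>A/C>T", ("C", "T"): "G>A/C>T",
    ("A", "C"): "A>C/T>G", ("T", "G"): "A>C/T>G",
    ("A", "T"): "A>T/T>A", ("T", "A"): "A>T/T>A",
    ("C", "G"): "C>G/G>C", ("G", "C"): "C>G/G>C",
    ("C", "A"): "C>A/G>T", ("G", "T"): "C>A/G>T",
}

SUBSTITUTION_PAIRS = ["A>G/T>C", "G>A/C>T", "A>C/T>G", "A>T/T>A", "C>G/G>C", "C>A/G>T"]


def substitution_class(ref: str, alt: str):
    """(pair label, is_transition, is_editing_pair) for a substitution.

    Transitions swap within purines or within pyrimidines; the A>G/T>C
    pair is the signature of A-to-I RNA editing.
    """
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    pair = _PAIR[(ref, alt)]
    is_transition = (ref in PURINES) == (alt in PURINES)
    return pair, is_transition, pair == "A>G/T>C"


def annotate_source(
    record: SvaseRecord,
    dna_sites: Optional[KnownSiteIndex] = None,
    editing_sites: Optional[KnownSiteIndex] = None,
) -> str:
    """Assign a source type from known-variant site lists.

    Exact (pos, ref, alt) matches label the record DNA-mutation-known
    and/or RNA-editing-known; a position-only match (allele orientation
    differs) is the weaker "position-known"; otherwise "novel".
    """
    labels = []
    position_only = False
    for idx, label in ((dna_sites, "DNA-mutation-known"), (editing_sites, "RNA-editing-known")):
        if idx is None:
            continue
        hit = idx.lookup(record.chrom, record.pos, record.ref, record.alt)
        if hit == "exact":
            labels.append(label)
        elif hit == "position":
            position_only = True
    if labels:
        return ";".join(labels)
    if position_only:
        return "position-known"
    return "novel"


def breakpoint_distances(record: SvaseRecord, junction: Junction) -> tuple:
    """(dist_to_breakpoint, dist_to_exon5, dist_to_exon3) for a record.

    The breakpoint is the intron boundary of the record's own side, with
    the base adjacent to the boundary at distance 1.  Exon-side distances
    run to the two ends of the anchor-covered exon segment (the only exon
    extent the caller knows without annotation), reported on the
    transcribed strand when it is known: exon 5' side is the end reached
    first by the polymerase.
    """
    if record.side == "left":
        dist_bp = junction.start - record.pos
    else:
        dist_bp = record.pos - junction.end + 1
    span = record.anchor_span
    if span is None:
        return dist_bp, None, None
    lo, hi = span
    dist_left = record.pos - lo + 1
    dist_right = hi - record.pos + 1
    if record.strand == "-":
        dist5, dist3 = dist_right, dist_left
    else:
        dist5, dist3 = dist_left, dist_right
    return dist_bp, dist5, dist3


def _tables_for(records: List[SvaseRecord], junctions: List[Junction]) -> Dict[str, pd.DataFrame]:
    junction_rows = [
        {
            "chrom": j.chrom,
            "intron_start": j.start,
            "intron_end": j.end,
            "depth": j.depth,
            "status": j.status,
            "motif": j.motif_class or "other",
            "strand": j.strand,
            "background_p": j.background_p,
        }
        for j in junctions
    ]
    jdf = pd.DataFrame(
        junction_rows,
        columns=[
            "chrom", "intron_start", "intron_end", "depth",
            "status", "motif", "strand", "background_p",
        ],
    )

    motif_counts = (
        jdf.groupby("motif").size().rename("n_junctions").reset_index()
        if len(jdf)
        else pd.DataFrame(columns=["motif", "n_junctions"])
    )
    depth_by_motif = (
        jdf.groupby("motif")["depth"].describe().reset_index()
        if len(jdf)
        else pd.DataFrame(columns=["motif"])
    )

    rec_rows = []
    for r in records:
        rec_rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos + 1,
                "ref": r.ref,
                "alt": r.alt,
                "subst_pair": r.subst_class,
                "is_transition": r.is_transition,
                "is_editing_pair": r.is_editing_pair,
                "dist_breakpoint": r.dist_breakpoint,
                "dist_exon5": r.dist_exon5,
                "dist_exon3": r.dist_exon3,
                "donor_ref": r.donor_ref,
                "donor_alt": r.donor_alt,
                "acceptor_ref": r.acceptor_ref,
                "acceptor_alt": r.acceptor_alt,
                "source_type": r.source_type,
                "junction_status": r.junction_status,
            }
        )
    rdf = pd.DataFrame(
        rec_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "subst_pair", "is_transition",
            "is_editing_pair", "dist_breakpoint", "dist_exon5", "dist_exon3",
            "donor_ref", "donor_alt", "acceptor_ref", "acceptor_alt",
            "source_type", "junction_status",
        ],
    )

    subs = Counter(r.subst_class for r in records if r.subst_class)
    subst_counts = pd.DataFrame(
        [{"subst_pair": p, "count": subs.get(p, 0)} for p in SUBSTITUTION_PAIRS]
    )
    n_rec = len(records)
    n_transition = sum(1 for r in records if r.is_transition)
    n_editing = sum(1 for r in records if r.is_editing_pair)
    summary = pd.DataFrame(
        [
            {"metric": "n_svase", "value": n_rec},
            {"metric": "transition_fraction", "value": n_transition / n_rec if n_rec else 0.0},
            {"metric": "editing_pair_fraction", "value": n_editing / n_rec if n_rec else 0.0},
            {"metric": "n_junctions", "value": len(junctions)},
        ]
    )

    dist_bp_by_type = (
        rdf.groupby("subst_pair")["dist_breakpoint"].describe().reset_index()
        if n_rec
        else pd.DataFrame(columns=["subst_pair"])
    )

    return {
        "junctions": jdf,
        "junction_depth_distribution": (
            jdf.groupby("depth").size().rename("n_junctions").reset_index()
            if len(jdf)
            else pd.DataFrame(columns=["depth", "n_junctions"])
        ),
        "junction_motif_counts": motif_counts,
        "junction_depth_by_motif": depth_by_motif,
        "svase_records": rdf,
        "signal_scores": rdf[
            ["chrom", "pos", "ref", "alt", "donor_ref", "donor_alt", "acceptor_ref", "acceptor_alt"]
        ],
        "substitution_counts": subst_counts,
        "breakpoint_distance_by_type": dist_bp_by_type,
        "summary": summary,
    }


def summarize(
    records: List[SvaseRecord],
    junctions: Dict,
    out_dir: Optional[str] = None,
) -> Dict[str, pd.DataFrame]:
    """Build every summary table, for all junctions and novel-only.

    Returns a dict of DataFrames keyed ``all_<name>`` / ``novel_<name>``;
    when ``out_dir`` is given each table is also written as TSV.
    """
    jlist = sorted(junctions.values(), key=lambda j: j.key)
    novel_j = [j for j in jlist if j.status != "known"]
    novel_r = [r for r in records if r.junction_status != "known"]

    tables: Dict[str, pd.DataFrame] = {}
    for prefix, recs, js in (("all", records, jlist), ("novel", novel_r, novel_j)):
        for name, df in _tables_for(recs, js).items():
            tables[f"{prefix}_{name}"] = df

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return tables
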