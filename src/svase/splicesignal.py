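"""Splice-signal classification and position-weight-matrix scoring.

Junctions are classified by their terminal intron dinucleotides (GT-AG,
its reverse complement CT-AC, and the minor GC-AG / AT-AC classes), which
also fixes the transcribed strand.  Donor and acceptor sites are scored
with first-order position weight matrices over the conventional windows
(donor: 3 exonic + 6 intronic bases; acceptor: 20 intronic + 3 exonic),
trained from annotated or discovered junctions with an additive
pseudocount and expressed as log2 odds against a uniform background.
The scorer is deliberately pluggable: any model exposing
``score_donor``/``score_acceptor`` over these windows can replace it.
Scores are annotation only — never a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .formats import GenomeIndex, revcomp

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}

DONOR_EXON = 3
DONOR_INTRON = 6
DONOR_LEN = DONOR_EXON + DONOR_INTRON  # 9
ACC_INTRON = 20
ACC_EXON = 3
ACC_LEN = ACC_INTRON + ACC_EXON  # 23

# (first two intron bases, last two intron bases) -> (class, strand)
_PLUS_MOTIFS = {
    ("GT", "AG"): "GT-AG",
    ("GC", "AG"): "GC-AG",
    ("AT", "AC"): "AT-AC",
}
# reverse complements of the plus-strand classes, seen on the genome strand
_MINUS_MOTIFS = {
    ("CT", "AC"): "CT-AC",       # minus-strand GT-AG
    ("CT", "GC"): "GC-AG(-)",
    ("GT", "AT"): "AT-AC(-)",
}


class WindowError(ValueError):
    """A scoring window would leave the contig."""


def motif_and_strand(key: Tuple[str, int, int], genome: GenomeIndex) -> Tuple[str, str]:
    """Classify the splice dinucleotides of an intron and infer strand.

    Returns (motif class, strand); non-canonical boundaries give
    ("other", ".").
    """
    chrom, start, end = key
    if end - start < 4:
        return "other", "."
    first = genome.fetch(chrom, start, start + 2)
    last = genome.fetch(chrom, end - 2, end)
    if (first, last) in _PLUS_MOTIFS:
        return _PLUS_MOTIFS[(first, last)], "+"
    if (first, last) in _MINUS_MOTIFS:
        return _MINUS_MOTIFS[(first, last)], "-"
    return "other", "."


def _fetch_sub(
    genome: GenomeIndex,
    chrom: str,
    start: int,
    end: int,
    override: Optional[Tuple[int, str]] = None,
) -> str:
    """Genome slice with an optional single-base substitution applied."""
    seq = genome.fetch(chrom, start, end)
    if override is not None:
        pos, base = override
        if start <= pos < end:
            i = pos - start
            seq = seq[:i] + base + seq[i + 1 :]
    return seq


def extract_site_windows(
    key: Tuple[str, int, int],
    strand: str,
    genome: GenomeIndex,
    override: Optional[Tuple[int, str]] = None,
) -> Tuple[str, str]:
    """Sense-strand donor 9-mer and acceptor 23-mer for an intron.

    On the plus strand the donor window surrounds the intron start and
    the acceptor window the intron end; on the minus strand the roles of
    the two genomic boundaries swap and windows are reverse-complemented
    so the model always sees transcribed-strand sequence.  ``override``
    optionally substitutes one genomic base (given on the genome strand)
    before orientation, for variant-allele scoring.
    """
    chrom, s, e = key
    length = len(genome.sequences[chrom])
    try:
        if strand == "+":
            if s - DONOR_EXON < 0 or e + ACC_EXON > length:
                raise WindowError(f"windows outside contig for {key}")
            donor = _fetch_sub(genome, chrom, s - DONOR_EXON, s + DONOR_INTRON, override)
            acceptor = _fetch_sub(genome, chrom, e - ACC_INTRON, e + ACC_EXON, override)
        elif strand == "-":
            if e + DONOR_EXON > length or s - ACC_EXON < 0:
                raise WindowError(f"windows outside contig for {key}")
            donor = revcomp(_fetch_sub(genome, chrom, e - DONOR_INTRON, e + DONOR_EXON, override))
            acceptor = revcomp(_fetch_sub(genome, chrom, s - ACC_EXON, s + ACC_INTRON, override))
        else:
            raise ValueError("strand must be '+' or '-'")
    except IndexError as exc:
        raise WindowError(str(exc)) from exc
    return donor, acceptor


@dataclass
class SpliceSignalModel:
    """Log2-odds PWMs for donor (9 x 4) and acceptor (23 x 4) windows."""

    donor: np.ndarray
    acceptor: np.ndarray
    pseudocount: float = 0.25
    n_train: int = 0

    def score_donor(self, seq: str) -> float:
        return _score(self.donor, seq)

    def score_acceptor(self, seq: str) -> float:
        return _score(self.acceptor, seq)


def _score(matrix: np.ndarray, seq: str) -> float:
    if len(seq) != matrix.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != window {matrix.shape[0]}")
    total = 0.0
    for i, b in enumerate(seq):
        idx = BASE_IDX.get(b)
        if idx is None:  # N or other ambiguity contributes the background (0 bits)
            continue
        total += matrix[i, idx]
    return float(total)


def uniform_model(pseudocount: float = 0.25) -> SpliceSignalModel:
    """Model with uniform base frequencies: every sequence scores 0 bits."""
    return SpliceSignalModel(
        donor=np.zeros((DONOR_LEN, 4)),
        acceptor=np.zeros((ACC_LEN, 4)),
        pseudocount=pseudocount,
        n_train=0,
    )


def _freq_matrix(seqs, length: int, pseudocount: float) -> np.ndarray:
    counts = np.full((length, 4), pseudocount, dtype=float)
    for seq in seqs:
        for i, b in enumerate(seq):
            idx = BASE_IDX.get(b)
            if idx is not None:
                counts[i, idx] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.log2(probs / 0.25)


def train_model(
    junction_keys_with_strand,
    genome: GenomeIndex,
    pseudocount: float = 0.25,
) -> SpliceSignalModel:
    """Train donor/acceptor PWMs from (key, strand) training junctions.

    Frequencies get an additive pseudocount (default 0.25) and are
    converted to log2 odds against the uniform 0.25 background.  Raises
    on an empty (or fully unusable) training set.
    """
    donors, acceptors = [], []
    for key, strand in junction_keys_with_strand:
        if strand not in "+-":
            continue
        try:
            d, a = extract_site_windows(key, strand, genome)
        except WindowError:
            continue
        donors.append(d)
        acceptors.append(a)
    if not donors:
        raise ValueError("no usable training junctions for the splice-signal model")
    return SpliceSignalModel(
        donor=_freq_matrix(donors, DONOR_LEN, pseudocount),
        acceptor=_freq_matrix(acceptors, ACC_LEN, pseudocount),
        pseudocount=pseudocount,
        n_train=len(donors),
    )


def train_from_known(known, genome: GenomeIndex, pseudocount: float = 0.25) -> SpliceSignalModel:
    """Train from an annotated junction set, inferring strand from motifs."""
    pairs = []
    for chrom, s, e, strand in sorted(known.junctions):
        if strand not in "+-":
            _, strand = motif_and_strand((chrom, s, e), genome)
        if strand in "+-":
            pairs.append(((chrom, s, e), strand))
    return train_model(pairs, genome, pseudocount)


def score_junction(
    key: Tuple[str, int, int],
    strand: str,
    model: SpliceSignalModel,
    genome: GenomeIndex,
) -> Tuple[Optional[float], Optional[float], str, str]:
    """Score a junction's donor and acceptor windows.

    For strand '.', both orientations are scored and the better total is
    reported with low confidence.  Returns (donor, acceptor, strand_used,
    confidence); windows leaving the contig give (None, None, strand, .).
    """
    if strand in "+-":
        try:
            d, a = extract_site_windows(key, strand, genome)
        except WindowError:
            return None, None, strand, "high"
        return model.score_donor(d), model.score_acceptor(a), strand, "high"
    best = None
    for st in "+-":
        try:
            d, a = extract_site_windows(key, st, genome)
        except WindowError:
            continue
        sd, sa = model.score_donor(d), model.score_acceptor(a)
        if best is None or sd + sa > best[0] + best[1]:
            best = (sd, sa, st)
    if best is None:
        return None, None, ".", "low"
    return best[0], best[1], best[2], "low"


def score_ref_vs_alt(record, model: SpliceSignalModel, genome: GenomeIndex) -> None:
    """Fill donor/acceptor scores for reference and variant alleles in place.

    If the variant lies inside a window, the ALT-substituted window is
    scored (substitution applied on the genome strand, orientation
    handled by the window extraction); otherwise the variant scores equal
    the reference scores.  Records whose junction strand is undetermined
    are scored in the better-scoring orientation, flagged low-confidence
    by the junction's own strand call.
    """
    strand = record.strand if record.strand in "+-" else None
    if strand is None:
        d, a, st, _conf = score_junction(record.junction, ".", model, genome)
        record.donor_ref, record.acceptor_ref = d, a
        if d is None:
            record.donor_alt = record.acceptor_alt = None
            return
        strand = st
    else:
        try:
            dseq, aseq = extract_site_windows(record.junction, strand, genome)
        except WindowError:
            record.donor_ref = record.acceptor_ref = None
            record.donor_alt = record.acceptor_alt = None
            return
        record.donor_ref = model.score_donor(dseq)
        record.acceptor_ref = model.score_acceptor(aseq)
    try:
        dseq2, aseq2 = extract_site_windows(
            record.junction, strand, genome, override=(record.pos, record.alt)
        )
    except WindowError:
        record.donor_alt = record.donor_ref
        record.acceptor_alt = record.acceptor_ref
        return
    record.donor_alt = model.score_donor(dseq2)
    record.acceptor_alt = model.score_acceptor(aseq2)


# ----------------------------------------------------------------------
# Plain-text model persistence
# ----------------------------------------------------------------------

def save_model(model: SpliceSignalModel, path) -> None:
    """Persist a model as a documented plain-text matrix file.

    Layout: comment header, then one line per window position:
    ``<site> <position> <A> <C> <G> <T>`` with log2-odds values.
    """
    with open(path, "w") as fh:
        fh.write("# splice-signal PWM (log2 odds vs uniform background)\n")
        fh.write(f"# pseudocount={model.pseudocount} n_train={model.n_train}\n")
        for name, mat in (("donor", model.donor), ("acceptor", model.acceptor)):
            for i in range(mat.shape[0]):
                vals = " ".join(f"{v:.10g}" for v in mat[i])
                fh.write(f"{name} {i} {vals}\n")


def load_model(path) -> SpliceSignalModel:
    donor = np.zeros((DONOR_LEN, 4))
    acceptor = np.zeros((ACC_LEN, 4))
    pseudocount, n_train = 0.25, 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("pseudocount="):
                        pseudocount = float(tok.split("=")[1])
                    elif tok.startswith("n_train="):
                        n_train = int(tok.split("=")[1])
                continue
            parts = line.split()
            if len(parts) != 6:
                continue
            name, i, vals = parts[0], int(parts[1]), [float(x) for x in parts[2:]]
            (donor if name == "donor" else acceptor)[i] = vals
    return SpliceSignalModel(donor, acceptor, pseudocount, n_train)
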