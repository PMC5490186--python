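"""Readers and writers for every external format the pipeline touches.

One internal convention everywhere: coordinates are 0-based, half-open.
Conversion happens only at format boundaries (BED is already 0-based
half-open; GTF/GFF and VCF are 1-based).  A splicing junction is keyed by
its intron interval ``(chrom, intron_start, intron_end)`` where
``intron_start`` is the first intronic base and ``intron_end`` is one past
the last intronic base.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Set, Tuple

import pysam
from Bio import SeqIO

from .readqc import AlignedRead

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ----------------------------------------------------------------------
# Genome
# ----------------------------------------------------------------------

@dataclass
class GenomeIndex:
    """In-memory genome: chromosome name -> uppercase nucleotide string."""

    sequences: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end); raises if the window leaves the contig."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"window [{start},{end}) outside contig {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def fetch_clamped(self, chrom: str, start: int, end: int) -> Tuple[int, str]:
        """Like fetch but truncated at contig edges; returns (actual_start, seq)."""
        seq = self.sequences[chrom]
        s = max(0, start)
        e = min(len(seq), end)
        return s, seq[s:e]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]


def load_genome(path) -> GenomeIndex:
    """Load a (multi-)FASTA into memory, uppercasing all sequences."""
    sequences: Dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name in FASTA: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeIndex(sequences)


def write_genome(genome: GenomeIndex, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome.sequences:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------------
# Alignments
# ----------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def _read_id(qname: str, flag: int) -> str:
    if flag & 0x40:
        return qname + "/1"
    if flag & 0x80:
        return qname + "/2"
    return qname


def read_alignments(path, genome: Optional[GenomeIndex] = None) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM or BAM file in file order.

    If a genome is supplied, every reference name used by a mapped record
    must exist in it.  Unmapped records are yielded with their unmapped
    flag intact so QC can tally them.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        if genome is not None:
            missing = [r for r in af.references if r not in genome]
            if missing:
                raise ValueError(
                    f"alignment references absent from genome: {', '.join(missing)}"
                )
        for rec in af:
            if rec.is_unmapped:
                yield AlignedRead(
                    read_id=_read_id(rec.query_name, rec.flag),
                    chrom=None,
                    pos=-1,
                    cigar=(),
                    seq=rec.query_sequence or "",
                    base_quals=tuple(rec.query_qualities or ()),
                    mapq=rec.mapping_quality,
                    flag=rec.flag,
                )
                continue
            cigar = tuple(
                (_CIGAR_OPS[op], length) for op, length in (rec.cigartuples or ())
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            yield AlignedRead(
                read_id=_read_id(rec.query_name, rec.flag),
                chrom=rec.reference_name,
                pos=rec.reference_start,
                cigar=cigar,
                seq=rec.query_sequence or "",
                base_quals=tuple(rec.query_qualities or ()),
                mapq=rec.mapping_quality,
                flag=rec.flag,
                mismatch_count=nm,
            )


# ----------------------------------------------------------------------
# Known junctions (GTF / GFF / BED)
# ----------------------------------------------------------------------

@dataclass
class KnownJunctionSet:
    """Annotated intron intervals, 0-based half-open, strand-aware."""

    junctions: Set[Tuple[str, int, int, str]] = field(default_factory=set)
    source_format: str = ""

    @property
    def intervals(self) -> Set[Tuple[str, int, int]]:
        return {(c, s, e) for c, s, e, _ in self.junctions}

    def __contains__(self, key: Tuple[str, int, int]) -> bool:
        return key in self.intervals

    def __len__(self) -> int:
        return len(self.junctions)


_GTF_TID = re.compile(r'transcript_id "([^"]+)"')
_GFF_PARENT = re.compile(r"Parent=([^;]+)")
_GFF_ID = re.compile(r"ID=([^;]+)")


def _introns_from_exons(exons) -> Iterator[Tuple[int, int]]:
    exons = sorted(exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < s2:
            yield e1, s2


def load_known_junctions(path, fmt: Optional[str] = None) -> KnownJunctionSet:
    """Load annotated introns from GTF, GFF or BED.

    GTF/GFF: introns between consecutive exons of each transcript (grouped
    by ``transcript_id`` / ``Parent``).  BED with < 12 columns: each record
    IS an intron interval.  BED12: introns between consecutive blocks.
    """
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt in ("gff3",):
        fmt = "gff"
    if fmt not in ("gtf", "gff", "bed"):
        raise ValueError(f"unknown known-junction format: {fmt}")

    out = KnownJunctionSet(source_format=fmt.upper())
    if fmt in ("gtf", "gff"):
        pattern = _GTF_TID if fmt == "gtf" else _GFF_PARENT
        groups: Dict[str, list] = {}
        strands: Dict[str, str] = {}
        chroms: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2].lower() != "exon":
                    continue
                m = pattern.search(f[8]) or _GFF_ID.search(f[8])
                if not m:
                    continue
                tid = m.group(1)
                # GTF/GFF are 1-based closed -> 0-based half-open exon
                groups.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
                strands[tid] = f[6] if f[6] in "+-" else "."
                chroms[tid] = f[0]
        for tid, exons in groups.items():
            for s, e in _introns_from_exons(exons):
                out.junctions.add((chroms[tid], s, e, strands[tid]))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                    exons = [
                        (start + bs, start + bs + sz)
                        for bs, sz in zip(starts, sizes)
                    ]
                    for s, e in _introns_from_exons(exons):
                        out.junctions.add((chrom, s, e, strand))
                else:
                    out.junctions.add((chrom, start, end, strand))
    return out


def write_junction_bed(junctions, path) -> None:
    """Write junction intron intervals as BED6 (score = read depth).

    ``junctions`` is an iterable of objects with chrom/start/end/depth and
    optional strand/status attributes, or plain (chrom, start, end) keys.
    """
    with open(path, "w") as fh:
        rows = []
        for j in junctions:
            if isinstance(j, tuple):
                chrom, start, end = j
                name, score, strand = "junction", 0, "."
            else:
                chrom, start, end = j.chrom, j.start, j.end
                name = getattr(j, "status", "junction") or "junction"
                score = getattr(j, "depth", 0)
                strand = getattr(j, "strand", ".") or "."
            rows.append((chrom, start, end, name, score, strand))
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")


# ----------------------------------------------------------------------
# Known variant sites (VCF / tabular)
# ----------------------------------------------------------------------

@dataclass
class KnownSiteIndex:
    """Single-nucleotide variant sites keyed by 0-based position.

    Matching is by position plus exact (ref, alt) pair; a position-only
    match is reported separately because public dumps vary in allele
    orientation.
    """

    sites: Dict[Tuple[str, int], Set[Tuple[str, str]]] = field(default_factory=dict)
    label: str = ""
    skipped: int = 0

    def add(self, chrom: str, pos0: int, ref: str, alt: str) -> None:
        self.sites.setdefault((chrom, pos0), set()).add((ref, alt))

    def lookup(self, chrom: str, pos0: int, ref: str, alt: str) -> Optional[str]:
        pairs = self.sites.get((chrom, pos0))
        if pairs is None:
            return None
        return "exact" if (ref, alt) in pairs else "position"

    def __len__(self) -> int:
        return sum(len(v) for v in self.sites.values())


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != alt and ref in "ACGT" and alt in "ACGT"


def load_known_sites(path, fmt: Optional[str] = None, label: str = "") -> KnownSiteIndex:
    """Load known SNV sites from VCF or a tabular chrom/pos/ref/alt file.

    Positions are 1-based in both dialects (VCF convention) and stored
    0-based.  Multi-allelic VCF rows expand to one (ref, alt) pair each;
    non-SNV rows are skipped and counted.
    """
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "vcf" if first.startswith("##fileformat") or str(path).endswith(".vcf") else "tsv"
    idx = KnownSiteIndex(label=label)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "vcf":
                    chrom, pos, ref, alts = f[0], int(f[1]), f[3].upper(), f[4]
                else:
                    chrom, pos, ref, alts = f[0], int(f[1]), f[2].upper(), f[3]
            except (IndexError, ValueError):
                idx.skipped += 1
                log.warning("skipping malformed known-site row: %r", line)
                continue
            for alt in alts.upper().split(","):
                if _is_snv(ref, alt):
                    idx.add(chrom, pos - 1, ref, alt)
                else:
                    idx.skipped += 1
    if idx.skipped:
        log.info("%s: skipped %d non-SNV or malformed entries", path, idx.skipped)
    return idx


def write_known_sites_tsv(idx: KnownSiteIndex, path) -> None:
    """Re-export a site index as tabular chrom/pos(1-based)/ref/alt."""
    with open(path, "w") as fh:
        for (chrom, pos0), pairs in sorted(idx.sites.items()):
            for ref, alt in sorted(pairs):
                fh.write(f"{chrom}\t{pos0 + 1}\t{ref}\t{alt}\n")


# ----------------------------------------------------------------------
# Result VCF
# ----------------------------------------------------------------------

_INFO_FIELDS = [
    ("JSTART", "1", "Integer", "Intron start of the associated junction (0-based)"),
    ("JEND", "1", "Integer", "Intron end of the associated junction (0-based, exclusive)"),
    ("SIDE", "1", "String", "Junction part carrying the variant (left=5'ss exon, right=3'ss exon)"),
    ("DEPTH", "1", "Integer", "Unmasked read depth at the site from junction-supporting reads"),
    ("ALTC", "1", "Integer", "ALT-supporting read count"),
    ("ALTF", "1", "Float", "ALT fraction among counted bases"),
    ("PVAR", "1", "Float", "Variant significance p (one-sided Fisher vs sequencing error)"),
    ("PASSOC", "1", "Float", "Variant-junction association p (one-sided Fisher)"),
    ("PBG", "1", "Float", "Junction background-expression p"),
    ("UNIVERSE", "1", "String", "Association read universe (target-only or related-total)"),
    ("NOCONTRAST", "0", "Flag", "No non-junction coverage at the site (association p set to 0)"),
    ("STATUS", "1", "String", "Junction status: known, novel or shift"),
    ("SHIFT", "1", "Integer", "Offset to the known junction for shift events"),
    ("MOTIF", "1", "String", "Splice dinucleotide class of the junction"),
    ("STRAND", "1", "String", "Inferred transcribed strand of the junction"),
    ("DONOR_REF", "1", "Float", "Donor-site PWM score, reference allele (bits)"),
    ("DONOR_ALT", "1", "Float", "Donor-site PWM score, variant allele (bits)"),
    ("ACC_REF", "1", "Float", "Acceptor-site PWM score, reference allele (bits)"),
    ("ACC_ALT", "1", "Float", "Acceptor-site PWM score, variant allele (bits)"),
    ("SRC", "1", "String", "Source type from known-site lists"),
]


def _fmt(x) -> str:
    if x is None:
        return "."
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_vcf(records, genome: GenomeIndex, path) -> None:
    """Write validated variant-junction associations as VCF 4.2.

    POS is 1-based; every INFO key is declared in the header.  The REF
    allele of every record is checked against the genome.
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in genome.lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for key, num, typ, desc in _INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    body = []
    for r in records:
        gbase = genome.base(r.chrom, r.pos)
        if gbase != r.ref:
            raise ValueError(
                f"REF mismatch at {r.chrom}:{r.pos + 1}: record {r.ref}, genome {gbase}"
            )
        info = [
            f"JSTART={r.junction[1]}",
            f"JEND={r.junction[2]}",
            f"SIDE={r.side}",
            f"DEPTH={r.depth}",
            f"ALTC={r.alt_count}",
            f"ALTF={_fmt(r.alt_fraction)}",
            f"PVAR={_fmt(r.p_variant)}",
            f"PASSOC={_fmt(r.p_association)}",
            f"PBG={_fmt(r.background_p)}",
            f"UNIVERSE={r.used_universe}",
        ]
        if r.no_contrast:
            info.append("NOCONTRAST")
        info.append(f"STATUS={r.junction_status}")
        if r.shift_offset is not None:
            info.append(f"SHIFT={r.shift_offset}")
        info += [
            f"MOTIF={_fmt(r.motif_class)}",
            f"STRAND={r.strand}",
            f"DONOR_REF={_fmt(r.donor_ref)}",
            f"DONOR_ALT={_fmt(r.donor_alt)}",
            f"ACC_REF={_fmt(r.acceptor_ref)}",
            f"ACC_ALT={_fmt(r.acceptor_alt)}",
            f"SRC={r.source_type}",
        ]
        body.append(
            f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{';'.join(info)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines + body) + "\n")


def read_svase_vcf(path) -> list:
    """Read back a result VCF into plain dicts (0-based positions)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            out.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "info": info,
                }
            )
    return out


# ----------------------------------------------------------------------
# Flanking sequence FASTA
# ----------------------------------------------------------------------

def write_flank_fasta(records, genome: GenomeIndex, path, flank_bp: int = 50) -> None:
    """Write reference- and variant-allele flanking windows for each record.

    For a variant at pos, the window is [pos - flank_bp, pos + flank_bp + 1)
    truncated at contig edges; two FASTA records are emitted per variant
    with the center base equal to REF and ALT respectively.  Useful for
    downstream exonic-splicing-enhancer motif prediction.
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    with open(path, "w") as fh:
        for r in records:
            start, seq = genome.fetch_clamped(
                r.chrom, r.pos - flank_bp, r.pos + flank_bp + 1
            )
            center = r.pos - start
            base_id = f"{r.chrom}_{r.pos + 1}_{r.ref}_{r.alt}"
            fh.write(f">{base_id}_ref\n{seq}\n")
            alt_seq = seq[:center] + r.alt + seq[center + 1 :]
            fh.write(f">{base_id}_alt\n{alt_seq}\n")
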