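"""Format boundaries: FASTA, SAM/BAM, GTF/GFF/BED, VCF, flanking output."""

import pysam
import pytest

from svase import formats
from svase.assoc import SvaseRecord
from svase.formats import GenomeIndex


def _record(chrom="chr1", pos=100, ref="G", alt="A", **kw):
    defaults = dict(
        junction=(chrom, 119, 219), side="left", depth=10, alt_count=5,
        alt_fraction=0.5, p_variant=0.01, p_association=0.01, consistent=True,
        used_universe="target-only", no_contrast=False, junction_status="novel",
        background_p=0.0,
    )
    defaults.update(kw)
    return SvaseRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


class TestGenome:
    def test_load_uppercases_and_reads_back(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n>chr2\nNNAA\n")
        g = formats.load_genome(p)
        assert g.sequences == {"chr1": "ACGT", "chr2": "NNAA"}
        assert g.lengths == {"chr1": 4, "chr2": 4}

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            formats.load_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            formats.load_genome(p)


class TestAlignments:
    HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
    LINE = "r1\t0\tchr1\t100\t60\t20M100N30M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tNM:i:1\n"

    def test_sam_parse_preserves_cigar_and_tags(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(self.HEADER + self.LINE)
        (read,) = formats.read_alignments(p)
        assert read.cigar == (("M", 20), ("N", 100), ("M", 30))
        assert read.pos == 99 and read.mismatch_count == 1
        assert len(read.cigar) == 3

    def test_bam_and_sam_yield_identical_records(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(self.HEADER + self.LINE)
        bam = tmp_path / "a.bam"
        with pysam.AlignmentFile(str(sam)) as fin:
            with pysam.AlignmentFile(str(bam), "wb", header=fin.header) as fout:
                for rec in fin:
                    fout.write(rec)
        (from_sam,) = formats.read_alignments(sam)
        (from_bam,) = formats.read_alignments(bam)
        assert from_sam == from_bam

    def test_unknown_reference_is_an_error(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:1000\n")
        genome = GenomeIndex({"chr1": "A" * 1000})
        with pytest.raises(ValueError, match="chrX"):
            list(formats.read_alignments(p, genome))


class TestKnownJunctions:
    def test_gtf_consecutive_exons_become_introns(self, tmp_path):
        p = tmp_path / "k.gtf"
        p.write_text(
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tsrc\texon\t201\t300\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tsrc\texon\t1\t50\t.\t+\t.\ttranscript_id "single";\n'
        )
        known = formats.load_known_junctions(p)
        assert known.junctions == {("chr1", 100, 200, "+")}

    def test_gff_parent_grouping_and_unsorted_exons(self, tmp_path):
        p = tmp_path / "k.gff3"
        p.write_text(
            "chr1\tsrc\texon\t201\t300\t.\t-\t.\tParent=t1\n"
            "chr1\tsrc\texon\t1\t100\t.\t-\t.\tParent=t1\n"
        )
        known = formats.load_known_junctions(p)
        assert known.junctions == {("chr1", 100, 200, "-")}

    def test_bed12_blocks(self, tmp_path):
        p = tmp_path / "k.bed"
        p.write_text(
            "chr1\t0\t300\tname\t0\t+\t0\t300\t0\t2\t100,100,\t0,200,\n"
        )
        known = formats.load_known_junctions(p)
        assert known.junctions == {("chr1", 100, 200, "+")}

    def test_plain_bed_rows_are_introns(self, tmp_path):
        p = tmp_path / "k.bed"
        p.write_text("chr1\t100\t200\tj\t5\t+\n")
        known = formats.load_known_junctions(p)
        assert ("chr1", 100, 200) in known

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            formats.load_known_junctions(tmp_path / "k.xyz", "xyz")

    def test_bed_round_trip_is_lossless(self, tmp_path, tiny_result):
        path = tmp_path / "junctions.bed"
        junctions = [tiny_result.junctions[k] for k in sorted(tiny_result.junctions)]
        formats.write_junction_bed(junctions, path)
        reloaded = formats.load_known_junctions(path, "bed")
        assert reloaded.intervals == set(tiny_result.junctions)


class TestKnownSites:
    VCF = (
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t101\t.\tA\tG\t.\t.\t.\n"
        "chr1\t201\t.\tA\tG,T\t.\t.\t.\n"
        "chr1\t301\t.\tA\tAT\t.\t.\t.\n"
    )

    def test_vcf_positions_shift_and_multiallelics_expand(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(self.VCF)
        idx = formats.load_known_sites(p)
        assert idx.sites[("chr1", 100)] == {("A", "G")}
        assert idx.sites[("chr1", 200)] == {("A", "G"), ("A", "T")}
        assert ("chr1", 300) not in idx.sites  # indel skipped
        assert idx.skipped == 1

    def test_tabular_re_export_produces_identical_index(self, tmp_path):
        p = tmp_path / "s.vcf"
        p.write_text(self.VCF)
        idx = formats.load_known_sites(p)
        tsv = tmp_path / "s.tsv"
        formats.write_known_sites_tsv(idx, tsv)
        idx2 = formats.load_known_sites(tsv)
        assert idx.sites == idx2.sites

    def test_lookup_distinguishes_exact_and_position(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chr1\t101\tA\tG\n")
        idx = formats.load_known_sites(p)
        assert idx.lookup("chr1", 100, "A", "G") == "exact"
        assert idx.lookup("chr1", 100, "G", "A") == "position"
        assert idx.lookup("chr1", 101, "A", "G") is None


class TestVcfOutput:
    def _genome(self):
        seq = list("A" * 400)
        seq[100] = "G"
        return GenomeIndex({"chr1": "".join(seq)})

    def test_pos_is_one_based_and_info_round_trips(self, tmp_path):
        genome = self._genome()
        path = tmp_path / "out.vcf"
        formats.write_vcf([_record()], genome, path)
        (rec,) = formats.read_svase_vcf(path)
        assert rec["pos"] == 100 and rec["ref"] == "G" and rec["alt"] == "A"
        assert rec["info"]["JSTART"] == 119 and rec["info"]["SIDE"] == "left"
        text = path.read_text()
        assert "\t101\t" in text
        for key in ("DEPTH", "PVAR", "PASSOC", "SRC"):
            assert f"##INFO=<ID={key}" in text

    def test_empty_record_list_gives_header_only(self, tmp_path):
        path = tmp_path / "out.vcf"
        formats.write_vcf([], self._genome(), path)
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_ref_mismatch_with_genome_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="REF mismatch"):
            formats.write_vcf(
                [_record(ref="T")], self._genome(), tmp_path / "out.vcf"
            )


class TestFlankFasta:
    def test_windows_center_and_substitute(self, tmp_path):
        genome = GenomeIndex({"chr1": "ACGT" * 2500})
        rec = _record(pos=100, ref=genome.base("chr1", 100), alt="T"
                      if genome.base("chr1", 100) != "T" else "C")
        path = tmp_path / "f.fa"
        formats.write_flank_fasta([rec], genome, path, flank_bp=50)
        entries = path.read_text().strip().split("\n")
        ref_seq, alt_seq = entries[1], entries[3]
        assert len(ref_seq) == len(alt_seq) == 101
        assert ref_seq[50] == rec.ref and alt_seq[50] == rec.alt
        assert ref_seq[:50] == alt_seq[:50] and ref_seq[51:] == alt_seq[51:]

    def test_contig_edge_truncates(self, tmp_path):
        genome = GenomeIndex({"chr1": "ACGTACGTACGT"})
        rec = _record(pos=3, ref="T", alt="A")
        path = tmp_path / "f.fa"
        formats.write_flank_fasta([rec], genome, path, flank_bp=50)
        ref_seq = path.read_text().strip().split("\n")[1]
        assert ref_seq == "ACGTACGTACGT"  # window clipped to the whole contig
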