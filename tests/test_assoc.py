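"""Consistency branch, association test and record assembly."""

import pytest

from conftest import make_read
from fisher_oracle import fisher_oracle
from svase.assoc import (
    AssocParams,
    ReadIndex,
    association_test,
    benjamini_hochberg,
    consistency_check,
    evaluate_candidate,
)
from svase.junctions import Junction
from svase.variants import VariantCandidate


class TestConsistency:
    def test_equal_frequencies_are_consistent(self):
        assert consistency_check((3, 3), (3, 3), AssocParams())

    def test_opposite_frequencies_are_inconsistent(self):
        # two-sided p = 2 / C(20,10) ~ 1.08e-5
        assert not consistency_check((10, 0), (0, 10), AssocParams())
        p = float(fisher_oracle(10, 0, 0, 10, "two-sided"))
        assert p == pytest.approx(2 / 184756, abs=1e-12)

    def test_zero_related_coverage_is_consistent_by_convention(self):
        assert consistency_check((10, 0), (0, 0), AssocParams())


class TestAssociationTest:
    def test_junction_enriched_alt_is_kept(self):
        p, flag = association_test((2, 0), (0, 5), AssocParams())
        assert p == pytest.approx(1 / 21, abs=1e-12)
        assert p <= 0.05 and not flag

    def test_alt_everywhere_is_dropped(self):
        p, flag = association_test((3, 0), (3, 0), AssocParams())
        assert p == 1.0 and not flag

    def test_no_contrast_convention(self):
        p, flag = association_test((5, 1), (0, 0), AssocParams())
        assert p == 0.0 and flag


class TestCandidateWiring:
    """End-to-end strata construction on hand-built reads."""

    def _setup(self, alt_in_related=0, alt_in_decoys=0):
        # target junction [119,219): 6 reads, all carrying ALT at 110
        reads = []
        for i in range(6):
            seq = list("G" * 50)
            seq[11] = "A"
            reads.append(make_read(read_id=f"t{i}", pos=99,
                                   cigar=(("M", 20), ("N", 100), ("M", 30)),
                                   seq="".join(seq)))
        # related junction [139, 219) shares the intron end; its longer left
        # anchor (105..139) also covers position 110
        for i in range(6):
            seq = list("G" * 50)
            if i < alt_in_related:
                seq[5] = "A"
            reads.append(make_read(read_id=f"rel{i}", pos=105,
                                   cigar=(("M", 34), ("N", 80), ("M", 16)),
                                   seq="".join(seq)))
        # non-split decoys covering 110
        for i in range(8):
            seq = list("G" * 50)
            if i < alt_in_decoys:
                seq[25] = "A"
            reads.append(make_read(read_id=f"d{i}", pos=85, seq="".join(seq)))
        target = Junction("chr1", 119, 219,
                          supporting={f"t{i}" for i in range(6)})
        related = Junction("chr1", 139, 219,
                           supporting={f"rel{i}" for i in range(6)})
        cand = VariantCandidate("chr1", 110, "G", "A", target.key, "left", 6, 6)
        return cand, target, related, ReadIndex(reads)

    def test_consistent_branch_contrasts_target_against_rest(self):
        cand, target, related, index = self._setup(alt_in_related=6)
        evaluate_candidate(cand, target, [related], index, AssocParams())
        assert cand.consistent and cand.used_universe == "target-only"
        assert cand.target_counts == (6, 0)
        assert cand.related_counts == (6, 0)
        # row2 = related (6 alt) + decoys (8 ref)
        expected = float(fisher_oracle(6, 0, 6, 8, "greater"))
        assert cand.p_association == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_branch_merges_related_into_row1(self):
        cand, target, related, index = self._setup(alt_in_related=0)
        evaluate_candidate(cand, target, [related], index, AssocParams())
        assert not cand.consistent and cand.used_universe == "related-total"
        # row1 = target + related = (6, 6); row2 = 8 ref decoys
        expected = float(fisher_oracle(6, 6, 0, 8, "greater"))
        assert cand.p_association == pytest.approx(expected, abs=1e-12)

    def test_genomic_snp_expressed_everywhere_is_rejected(self):
        """Uniform ALT across junction and non-junction reads: no association."""
        cand, target, related, index = self._setup(alt_in_related=6, alt_in_decoys=8)
        evaluate_candidate(cand, target, [related], index, AssocParams())
        assert cand.consistent
        assert cand.p_association > 0.5

    def test_junction_private_site_kept_via_no_contrast(self):
        cand, target, _, index = self._setup()
        # only target-junction reads cover the site: no related, no decoys
        index2 = ReadIndex([r for r in index.reads.values()
                            if r.read_id.startswith("t")])
        evaluate_candidate(cand, target, [], index2, AssocParams())
        assert cand.consistent  # zero related coverage
        assert cand.no_contrast and cand.p_association == 0.0


class TestAssembly:
    def test_bh_adjustment_values(self):
        assert benjamini_hochberg([0.01, 0.04, 0.5]) == pytest.approx(
            [0.03, 0.06, 0.5], abs=1e-12
        )

    def test_bh_flag_applies_adjusted_cut(self):
        from svase.junctions import Junction
        from svase.assoc import assemble_records

        j = Junction("chr1", 119, 219, supporting={"a", "b", "c"},
                     background_p=0.0)
        table = {j.key: j}
        cands = []
        for i, p in enumerate((0.01, 0.04, 0.5)):
            c = VariantCandidate("chr1", 100 + i, "G", "A", j.key, "left", 10, 5)
            c.p_variant, c.p_association = 0.001, p
            c.consistent, c.used_universe = True, "target-only"
            cands.append(c)
        raw = assemble_records(cands, table, AssocParams())
        assert [r.pos for r in raw] == [100, 101]  # 0.01 and 0.04 pass raw cut
        bh = assemble_records(cands, table, AssocParams(multiple_testing="BH"))
        assert [r.pos for r in bh] == [100]  # adjusted 0.06 fails at alpha 0.05

    def test_same_site_two_junctions_both_reported(self):
        from svase.assoc import assemble_records

        j1 = Junction("chr1", 119, 219, supporting=set("abc"), background_p=0.0)
        j2 = Junction("chr1", 139, 219, supporting=set("xyz"), background_p=0.0)
        table = {j1.key: j1, j2.key: j2}
        cands = []
        for j in (j1, j2):
            c = VariantCandidate("chr1", 110, "G", "A", j.key, "left", 3, 3)
            c.p_variant, c.p_association = 0.01, 0.01
            c.consistent, c.used_universe = True, "target-only"
            cands.append(c)
        recs = assemble_records(cands, table, AssocParams())
        assert len(recs) == 2 and {r.junction for r in recs} == {j1.key, j2.key}

    def test_empty_candidate_list(self):
        from svase.assoc import assemble_records

        assert assemble_records([], {}, AssocParams()) == []
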