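"""Junction discovery, depth/background filtering and shift detection."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read
from fisher_oracle import fisher_oracle
from svase.formats import GenomeIndex, KnownJunctionSet
from svase.junctions import (
    Junction,
    JunctionParams,
    MalformedAlignmentError,
    aggregate_junctions,
    apply_background_filter,
    background_test,
    build_related_index,
    classify_vs_known,
    detect_shift,
    junctions_from_read,
    related_keys,
)


class TestJunctionsFromRead:
    def test_single_gap_coordinates_and_anchors(self):
        read = make_read(pos=99, cigar=(("M", 20), ("N", 100), ("M", 30)))
        (obs,) = junctions_from_read(read, min_anchor=8)
        assert (obs.intron_start, obs.intron_end) == (119, 219)
        assert (obs.left_anchor, obs.right_anchor) == (20, 30)

    def test_short_anchor_drops_observation(self):
        read = make_read(pos=99, cigar=(("M", 5), ("N", 100), ("M", 45)))
        assert junctions_from_read(read, min_anchor=8) == []
        assert len(junctions_from_read(read, min_anchor=5)) == 1

    def test_multi_gap_shares_middle_anchor(self):
        read = make_read(pos=0, cigar=(("M", 15), ("N", 50), ("M", 10), ("N", 60), ("M", 20)))
        obs = junctions_from_read(read, min_anchor=8)
        assert [(o.intron_start, o.intron_end) for o in obs] == [(15, 65), (75, 135)]
        assert (obs[0].left_anchor, obs[0].right_anchor) == (15, 10)
        assert (obs[1].left_anchor, obs[1].right_anchor) == (10, 20)

    def test_non_split_read_yields_nothing(self):
        assert junctions_from_read(make_read(), 8) == []

    @pytest.mark.parametrize(
        "cigar", [(("N", 100), ("M", 50)), (("M", 25), ("N", 100)),
                  (("M", 20), ("N", 50), ("N", 50), ("M", 30))]
    )
    def test_gap_at_read_edge_is_malformed(self, cigar):
        qlen = sum(n for op, n in cigar if op == "M")
        read = make_read(cigar=cigar, seq="A" * qlen, quals=(40,) * qlen)
        with pytest.raises(MalformedAlignmentError):
            junctions_from_read(read, 8)


class TestAggregate:
    def _obs(self, read_id, key=("chr1", 119, 219)):
        read = make_read(read_id=read_id, pos=key[1] - 20,
                         cigar=(("M", 20), ("N", key[2] - key[1]), ("M", 30)))
        return junctions_from_read(read, 8)[0]

    def test_depth_counts_distinct_reads(self):
        obs = [self._obs(f"r{i}") for i in range(5)]
        table = aggregate_junctions(obs, JunctionParams())
        assert table[("chr1", 119, 219)].depth == 5

    def test_low_depth_junctions_discarded(self):
        obs = [self._obs(f"r{i}") for i in range(2)]
        assert aggregate_junctions(obs, JunctionParams()) == {}

    def test_duplicate_observation_from_one_read_counts_once(self):
        obs = [self._obs("r1"), self._obs("r1"), self._obs("r2"), self._obs("r3")]
        table = aggregate_junctions(obs, JunctionParams())
        assert table[("chr1", 119, 219)].depth == 3


class TestRelatedSets:
    def _table(self):
        mk = lambda s, e: Junction("chr1", s, e, supporting={f"{s}-{e}-{i}" for i in range(5)})
        js = [mk(100, 200), mk(150, 200), mk(50, 200), mk(100, 300), mk(400, 500)]
        return {j.key: j for j in js}

    def test_combined_union_of_shared_boundaries(self):
        table = self._table()
        a = table[("chr1", 100, 200)]
        assert related_keys(a, table) == {
            ("chr1", 150, 200), ("chr1", 50, 200), ("chr1", 100, 300)
        }

    def test_left_part_competes_among_shared_intron_end(self):
        table = self._table()
        a = table[("chr1", 100, 200)]
        assert related_keys(a, table, side="left") == {
            ("chr1", 150, 200), ("chr1", 50, 200)
        }
        assert related_keys(a, table, side="right") == {("chr1", 100, 300)}

    def test_unique_junction_has_empty_set(self):
        table = self._table()
        assert related_keys(table[("chr1", 400, 500)], table) == set()

    def test_index_matches_per_junction_queries(self):
        table = self._table()
        idx = build_related_index(table)
        for key, j in table.items():
            assert idx[key]["combined"] == related_keys(j, table)
            assert idx[key]["left"] == related_keys(j, table, "left")


class TestBackgroundTest:
    def _j(self, depth, start=100, end=200):
        return Junction("chr1", start, end,
                        supporting={f"r{start}-{i}" for i in range(depth)})

    def test_no_competition_keeps_with_p_zero(self):
        assert background_test(self._j(3), [], JunctionParams()) == 0.0

    def test_clean_split_table_matches_closed_form(self):
        # depth 10 vs related 10, background 1% -> b = 1:
        # the one-sided p of [[10, 10], [1, 19]] by exact enumeration
        p = background_test(self._j(10), [self._j(10, 300, 400)], JunctionParams())
        expected = float(fisher_oracle(10, 10, 1, 19, "greater"))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_low_share_among_deep_relatives_is_background(self):
        related = [self._j(149, 300, 400), self._j(148, 500, 600)]
        j = self._j(3)
        p = background_test(j, related, JunctionParams())
        expected = float(fisher_oracle(3, 297, 3, 297, "greater"))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p > 0.05  # filtered out as background expression

    @given(depth=st.integers(1, 12), rel=st.integers(0, 18))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, depth, rel):
        import math
        j = self._j(depth)
        related = [self._j(rel, 300, 400)] if rel else []
        p = background_test(j, related, JunctionParams())
        if not related:
            assert p == 0.0
            return
        n = depth + rel
        b = math.ceil(0.01 * n)
        expected = float(fisher_oracle(depth, n - depth, b, n - b, "greater"))
        assert p == pytest.approx(expected, abs=1e-9)

    def test_filter_records_p_and_drops_background(self):
        table = {}
        for j in [self._j(3), self._j(200, 100, 300), self._j(150, 100, 400)]:
            table[j.key] = j
        kept = apply_background_filter(table, JunctionParams())
        assert ("chr1", 100, 200) not in kept  # 3 of 353 reads is background
        assert all(j.background_p is not None for j in kept.values())


class TestClassifyAndShift:
    def _known(self, *intervals):
        k = KnownJunctionSet()
        for chrom, s, e in intervals:
            k.junctions.add((chrom, s, e, "+"))
        return k

    def test_exact_match_is_known_off_by_one_is_novel(self):
        known = self._known(("chr1", 100, 200))
        table = {j.key: j for j in [Junction("chr1", 100, 200), Junction("chr1", 100, 201)]}
        out = classify_vs_known(table, known, keep_known=True)
        assert out[("chr1", 100, 200)].status == "known"
        assert out[("chr1", 100, 201)].status == "novel"

    def test_novel_only_mode_drops_known(self):
        known = self._known(("chr1", 100, 200))
        table = {j.key: j for j in [Junction("chr1", 100, 200), Junction("chr1", 300, 400)]}
        out = classify_vs_known(table, known, keep_known=False)
        assert set(out) == {("chr1", 300, 400)}

    def _genome(self, repeat=True):
        seq = list("ACGT" * 100)
        seq[100:102] = "AG"
        seq[200:202] = "AG" if repeat else "TT"
        return GenomeIndex({"chr1": "".join(seq)})

    def test_boundary_repeat_yields_shift(self):
        known = self._known(("chr1", 100, 200))
        hit = detect_shift(Junction("chr1", 102, 202), known, self._genome(), 10)
        assert hit == (("chr1", 100, 200), 2)

    def test_incompatible_sequence_yields_none(self):
        known = self._known(("chr1", 100, 200))
        assert detect_shift(Junction("chr1", 102, 202), known, self._genome(False), 10) is None

    def test_length_mismatch_yields_none(self):
        known = self._known(("chr1", 100, 201))
        assert detect_shift(Junction("chr1", 102, 202), known, self._genome(), 10) is None

    def test_shift_is_translation_invariant(self):
        """Shifting genome and annotation by a constant changes nothing."""
        base = self._genome()
        offset = 8
        shifted = GenomeIndex({"chr1": "C" * offset + base.sequences["chr1"]})
        known = self._known(("chr1", 100 + offset, 200 + offset))
        hit = detect_shift(
            Junction("chr1", 102 + offset, 202 + offset), known, shifted, 10
        )
        assert hit == (("chr1", 100 + offset, 200 + offset), 2)

    def test_positive_offset_wins_ties(self):
        # make both +1 and -1 valid: known introns at 99..199 and 101..201
        seq = list("A" * 400)
        genome = GenomeIndex({"chr1": "".join(seq)})  # all-A: every repeat holds
        known = self._known(("chr1", 99, 199), ("chr1", 101, 201))
        hit = detect_shift(Junction("chr1", 100, 200), known, genome, 10)
        assert hit == (("chr1", 99, 199), 1)
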