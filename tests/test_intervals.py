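"""Interval-set semantics: merging, consensus, overlap statistics, shuffles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tagbench as tb
from tagbench.intervals import IntervalSet

import oracles
from conftest import random_intervals


def iset(*records):
    return IntervalSet.from_records(list(records))


class TestIntervalSetBasics:
    def test_rejects_empty_or_inverted_intervals(self):
        with pytest.raises(ValueError):
            iset(("chr1", 10, 10))
        with pytest.raises(ValueError):
            iset(("chr1", 20, 10))

    def test_merge_joins_overlapping_and_bookended(self):
        merged = iset(("chr1", 0, 10), ("chr1", 10, 20), ("chr1", 25, 30),
                      ("chr1", 28, 40)).merge()
        assert [(r.chrom, r.start, r.end) for r in merged] == [
            ("chr1", 0, 20), ("chr1", 25, 40)]
        assert merged.is_merged

    def test_total_bp_counts_overlaps_once(self):
        assert iset(("chr1", 0, 100), ("chr1", 50, 150)).total_bp() == 150

    def test_bed_roundtrip(self, tmp_path):
        original = iset(("chr1", 5, 50, 3.5), ("chr2", 0, 10, 1.0))
        path = tmp_path / "peaks.bed"
        tb.write_bed(original, path, names=True)
        back = tb.read_bed(path)
        assert back == original
        assert list(back.df["score"]) == [3.5, 1.0]

    def test_read_bed_reports_malformed_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\tX\t5\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            tb.read_bed(path)


class TestConsensus:
    def test_interval_in_half_of_libraries_retained(self):
        shared = ("chr1", 100, 200)
        sets = [iset(shared), iset(shared), iset(("chr1", 500, 600)),
                iset(("chr1", 700, 800))]
        consensus = tb.multi_consensus(sets, min_count=2)
        assert [(r.chrom, r.start, r.end) for r in consensus] == [shared]

    def test_min_count_one_is_merged_union(self, rng):
        sets = [IntervalSet.from_records(random_intervals(rng, 8)) for _ in range(3)]
        union = IntervalSet(
            __import__("pandas").concat([s.df for s in sets])
        ).merge()
        assert tb.multi_consensus(sets, min_count=1) == union

    def test_default_rule_is_at_least_half(self):
        assert tb.default_min_count(8) == 4
        assert tb.default_min_count(7) == 4
        assert tb.default_min_count(1) == 1

    def test_consensus_nested_in_min_count(self, rng):
        sets = [IntervalSet.from_records(random_intervals(rng, 10)) for _ in range(5)]
        for k in range(2, 6):
            hi = tb.multi_consensus(sets, min_count=k)
            lo = tb.multi_consensus(sets, min_count=k - 1)
            # base-pair containment
            assert hi.intersect_bp(lo) == hi.total_bp()

    def test_matches_per_bp_oracle(self, rng):
        for _ in range(10):
            sets = [random_intervals(rng, int(rng.integers(1, 8)),
                                     chrom_len=2000, chroms=("chr1",), max_w=300)
                    for _ in range(int(rng.integers(2, 6)))]
            k = int(rng.integers(1, len(sets) + 1))
            expected = oracles.bf_consensus(sets, k, 2000)
            got = tb.multi_consensus([IntervalSet.from_records(s) for s in sets], k)
            assert [(r.chrom, r.start, r.end) for r in got] == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tb.multi_consensus([], min_count=1)


class TestPrecisionRecall:
    def test_definitional_values(self):
        # 9 of 10 query peaks overlap a reference; 8 of 10 reference peaks hit
        reference = iset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
        query_rows = [("chr1", i * 1000 + 50, i * 1000 + 150) for i in range(8)]
        query_rows += [("chr1", 7025, 7075)]          # second hit on ref 7
        query_rows += [("chr2", 0, 100)]              # miss
        query = iset(*query_rows)
        pr = tb.precision_recall_f1(query, reference)
        assert pr.precision == pytest.approx(0.9)
        assert pr.recall == pytest.approx(0.8)
        assert pr.f1 == pytest.approx(2 * 0.9 * 0.8 / 1.7)

    def test_identity_scores_one(self, rng):
        s = IntervalSet.from_records(random_intervals(rng, 12)).merge()
        pr = tb.precision_recall_f1(s, s)
        assert (pr.precision, pr.recall, pr.f1) == (1.0, 1.0, 1.0)

    def test_empty_sets_flagged_undefined(self):
        some = iset(("chr1", 0, 10))
        pr = tb.precision_recall_f1(IntervalSet(), some)
        assert not pr.precision_defined and math.isnan(pr.precision)
        pr = tb.precision_recall_f1(some, IntervalSet())
        assert not pr.recall_defined and math.isnan(pr.recall)


class TestJaccard:
    def test_known_values(self):
        a, b = iset(("chr1", 0, 100)), iset(("chr1", 50, 150))
        assert tb.jaccard(a, b) == pytest.approx(50 / 150)
        assert tb.jaccard(a, a) == 1.0
        assert tb.jaccard(a, iset(("chr2", 0, 100))) == 0.0
        assert math.isnan(tb.jaccard(IntervalSet(), IntervalSet()))

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = IntervalSet.from_records(random_intervals(rng, 6))
        b = IntervalSet.from_records(random_intervals(rng, 6))
        assert tb.jaccard(a, b) == tb.jaccard(b, a)
        assert tb.jaccard(a, b) == pytest.approx(
            oracles.bf_jaccard(
                [(r.chrom, r.start, r.end) for r in a],
                [(r.chrom, r.start, r.end) for r in b],
            )
        )


class TestShuffle:
    def test_widths_conserved_and_no_clashes(self, small_layout, rng):
        src = IntervalSet.from_records(
            random_intervals(rng, 30, chrom_len=900_000, max_w=800)
        )
        shuf = tb.shuffle_intervals(src, small_layout,
                                    exclude=small_layout.blacklist, seed=5)
        assert sorted(shuf.widths()) == sorted(src.widths())
        records = [(r.chrom, r.start, r.end) for r in shuf]
        assert oracles.bf_self_overlap_pairs(records) == 0
        excl = [(r.chrom, r.start, r.end) for r in small_layout.blacklist]
        assert oracles.bf_overlap_pairs(records, excl) == 0

    def test_seed_contract(self, small_layout, rng):
        src = IntervalSet.from_records(random_intervals(rng, 15, chrom_len=900_000))
        a = tb.shuffle_intervals(src, small_layout, seed=1)
        b = tb.shuffle_intervals(src, small_layout, seed=1)
        c = tb.shuffle_intervals(src, small_layout, seed=2)
        assert a == b
        assert a != c

    def test_impossible_placement_raises(self):
        layout = tb.GenomeLayout((("chr1", 100),))
        src = iset(("chr1", 0, 90), ("chr1", 0, 90))
        with pytest.raises(tb.PlacementError):
            tb.shuffle_intervals(src, layout, seed=0, max_tries=50)


class TestFisher:
    def test_identical_sets_have_empty_off_diagonal(self, small_layout, rng):
        s = IntervalSet.from_records(
            random_intervals(rng, 10, chrom_len=900_000)
        ).merge()
        table, p = tb.fisher_overlap(s, s, small_layout)
        assert table[0, 1] == 0 and table[1, 0] == 0
        assert p < 1e-6

    def test_p_matches_exact_enumeration(self):
        # the package routes the p-value through the observed overlap table;
        # check the tail-summation convention against exhaustive enumeration
        from scipy.stats import fisher_exact

        for table in ([[5, 1], [1, 93]], [[2, 8], [6, 84]], [[10, 0], [0, 10]]):
            p_pkg = fisher_exact(np.array(table), alternative="two-sided")[1]
            p_oracle = oracles.bf_fisher_two_sided(table)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-10)

    def test_empty_input_rejected(self, small_layout):
        with pytest.raises(ValueError):
            tb.fisher_overlap(IntervalSet(), iset(("chr1", 0, 10)), small_layout)


class TestBenchmarkBundle:
    def test_report_row_contains_shuffle_quantiles(self, small_layout, rng):
        q = IntervalSet.from_records(random_intervals(rng, 20, chrom_len=900_000))
        r = IntervalSet.from_records(random_intervals(rng, 20, chrom_len=900_000))
        res = tb.benchmark(q.merge(), r.merge(), small_layout, n_shuffle=5, seed=3)
        row = res.to_row()
        assert {"precision", "recall", "f1", "jaccard", "fisher_p",
                "shuffled_f1_q95"} <= set(row)
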