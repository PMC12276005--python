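"""Coverage binning, CPM conservation, FRiP, count matrices, size factors."""

import numpy as np
import pandas as pd
import pytest

import tagbench as tb
from tagbench.intervals import IntervalSet

import oracles
from conftest import random_intervals

LAYOUT1 = tb.GenomeLayout((("chr1", 1000),))


def lib_of(rows, **kw):
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_count"])
    return tb.FragmentLibrary(frame, **kw)


class TestBinning:
    def test_span_mode_touches_every_overlapped_bin(self):
        lib = lib_of([("chr1", 100, 260, 1)])
        track = tb.fragments_to_coverage(lib, LAYOUT1, bin_size=50, mode="span")
        assert list(np.flatnonzero(track.values["chr1"])) == [2, 3, 4, 5]

    def test_midpoint_mode_single_bin_left_biased(self):
        lib = lib_of([("chr1", 100, 260, 1)])  # midpoint 180 -> bin 3
        track = tb.fragments_to_coverage(lib, LAYOUT1, bin_size=50, mode="midpoint")
        assert list(np.flatnonzero(track.values["chr1"])) == [3]

    def test_cpm_identity_four_fragments(self):
        lib = lib_of([("chr1", i * 200, i * 200 + 100, 1) for i in range(4)])
        track = tb.fragments_to_coverage(
            lib, LAYOUT1, bin_size=50, mode="midpoint", normalization="cpm"
        )
        vec = track.values["chr1"]
        assert set(vec[vec > 0]) == {250_000.0}
        assert vec.sum() == pytest.approx(1e6)

    def test_cpm_conserved_on_simulated_library(self, small_layout, small_library):
        track = tb.fragments_to_coverage(
            small_library, small_layout, bin_size=50, mode="midpoint",
            normalization="cpm",
        )
        assert track.total() == pytest.approx(1e6, rel=1e-9)

    def test_out_of_bounds_fragment_named_in_error(self):
        lib = lib_of([("chr1", 900, 1100, 1)])
        with pytest.raises(ValueError, match="chr1:900-1100"):
            tb.fragments_to_coverage(lib, LAYOUT1, bin_size=50)

    def test_bedgraph_roundtrip(self, tmp_path):
        lib = lib_of([("chr1", 0, 100, 2), ("chr1", 400, 500, 1)])
        track = tb.fragments_to_coverage(lib, LAYOUT1, bin_size=50, mode="span")
        path = tmp_path / "t.bedgraph"
        tb.write_bedgraph(track, path)
        back = tb.read_bedgraph(path, 50, LAYOUT1)
        assert np.array_equal(back.values["chr1"], track.values["chr1"])


class TestFrip:
    def test_extremes(self):
        lib = lib_of([("chr1", 0, 100, 1), ("chr1", 200, 300, 1)])
        inside = IntervalSet.from_records([("chr1", 0, 400)])
        outside = IntervalSet.from_records([("chr1", 500, 600)])
        assert tb.frip(lib, inside) == 1.0
        assert tb.frip(lib, outside) == 0.0

    def test_matches_per_fragment_brute_force(self, rng):
        rows = [(c, s, e, 1) for c, s, e in random_intervals(rng, 100, chrom_len=5000)]
        lib = lib_of(rows)
        peaks = IntervalSet.from_records(random_intervals(rng, 10, chrom_len=5000))
        expected = sum(
            any(oracles.overlaps((r.chrom, r.start, r.end), (p.chrom, p.start, p.end))
                for p in peaks)
            for r in lib.frame.itertuples()
        ) / len(lib)
        assert tb.frip(lib, peaks) == pytest.approx(expected)

    def test_monotone_under_peak_union(self, rng):
        rows = [(c, s, e, 1) for c, s, e in random_intervals(rng, 60, chrom_len=5000)]
        lib = lib_of(rows)
        a = IntervalSet.from_records(random_intervals(rng, 5, chrom_len=5000))
        b = IntervalSet.from_records(random_intervals(rng, 5, chrom_len=5000))
        union = IntervalSet(pd.concat([a.df, b.df])).merge()
        assert tb.frip(lib, union) >= tb.frip(lib, a) - 1e-12

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            tb.frip(tb.FragmentLibrary(None), IntervalSet())


class TestCountMatrix:
    def test_empty_regions_zero_rows(self):
        lib = lib_of([("chr1", 0, 100, 1)])
        cm = tb.count_matrix([lib], IntervalSet())
        assert cm.data.shape == (0, 1)

    def test_whole_chromosome_region_sums_all_reads(self, small_layout, small_library):
        regions = IntervalSet.from_records(
            [(c, 0, length) for c, length in small_layout.chromosomes]
        )
        cm = tb.count_matrix([small_library], regions)
        assert cm.data.iloc[:, 0].sum() == small_library.total_reads

    def test_overlapping_regions_rejected(self):
        lib = lib_of([("chr1", 0, 100, 1)])
        regions = IntervalSet.from_records([("chr1", 0, 100), ("chr1", 50, 150)])
        with pytest.raises(ValueError, match="merge"):
            tb.count_matrix([lib], regions)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            libs = [
                lib_of([(c, s, e, int(rng.integers(1, 4)))
                        for c, s, e in random_intervals(rng, 40, chrom_len=4000)],
                       library_id=f"l{i}")
                for i in range(3)
            ]
            regions = IntervalSet.from_records(
                random_intervals(rng, 12, chrom_len=4000)
            ).merge()
            cm = tb.count_matrix(libs, regions)
            expected = oracles.bf_count_matrix(
                [lib.frame for lib in libs],
                [(r.chrom, r.start, r.end) for r in regions],
            )
            assert cm.data.to_numpy().tolist() == expected


class TestSizeFactors:
    def test_identical_libraries_unit_factors(self, small_layout, small_library):
        libs = [small_library.replace(small_library.frame) for _ in range(3)]
        for i, lib in enumerate(libs):
            lib.library_id = f"l{i}"
        factors = tb.background_size_factors(libs, small_layout)
        assert np.allclose(factors, 1.0)

    def test_doubling_reads_doubles_factor(self, small_layout, small_library):
        doubled = small_library.replace(
            small_library.frame.assign(copy_count=small_library.frame["copy_count"] * 2)
        )
        doubled.library_id = "doubled"
        factors = tb.background_size_factors([small_library, doubled], small_layout)
        assert factors["doubled"] / factors["unit"] == pytest.approx(2.0)

    def test_depth_series_recovers_ratios(self, small_layout, small_library):
        libs = []
        for mult in (1, 2, 4):
            lib = small_library.replace(
                small_library.frame.assign(
                    copy_count=small_library.frame["copy_count"] * mult
                )
            )
            lib.library_id = f"x{mult}"
            libs.append(lib)
        f = tb.background_size_factors(libs, small_layout)
        assert f["x2"] / f["x1"] == pytest.approx(2.0, rel=0.05)
        assert f["x4"] / f["x1"] == pytest.approx(4.0, rel=0.05)

    def test_single_library_rejected(self, small_layout, small_library):
        with pytest.raises(ValueError):
            tb.background_size_factors([small_library], small_layout)


class TestCorrelation:
    def test_hand_computed_three_regions(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 3.0]})
        regions = IntervalSet.from_records(
            [("chr1", i * 100, i * 100 + 50) for i in range(3)]
        )
        cm = tb.CountMatrix(regions, data)
        corr = tb.correlation_matrix(cm)
        # hand Pearson: means (7/3, 2); sum of cross-deviations 2;
        # sums of squared deviations 14/3 and 2
        expected = 2 / np.sqrt((14 / 3) * 2)
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert corr.loc["a", "a"] == 1.0

    def test_scaled_column_perfectly_correlated(self):
        data = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [2.0, 10.0, 4.0]})
        regions = IntervalSet.from_records(
            [("chr1", i * 100, i * 100 + 50) for i in range(3)]
        )
        corr = tb.correlation_matrix(tb.CountMatrix(regions, data))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        regions = IntervalSet.from_records([("chr1", 0, 50), ("chr1", 100, 150)])
        corr = tb.correlation_matrix(tb.CountMatrix(regions, data))
        assert np.isnan(corr.loc["a", "b"])
        assert np.isnan(corr.loc["b", "b"])
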