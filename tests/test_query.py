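import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_table
from genotracks.core import GenomicRange, make_column_table
from genotracks.query import (
    build_index,
    group_overlapping_points,
    overlap_query,
    summarize,
)
from oracles import brute_overlap, brute_summarize


class TestOverlapQuery:
    def test_empty_table(self):
        idx = build_index(make_column_table([], [], [], {}))
        assert overlap_query(idx, GenomicRange("chr1", 0, 100)).size == 0

    def test_single_row_exact(self):
        idx = build_index(make_column_table(["chr1"], [10], [20], {}))
        assert list(overlap_query(idx, GenomicRange("chr1", 10, 20))) == [0]

    def test_half_open_boundary(self):
        t = make_column_table(["chr1", "chr1"], [0, 10], [10, 20], {})
        idx = build_index(t)
        assert list(overlap_query(idx, GenomicRange("chr1", 10, 11))) == [1]
        assert list(overlap_query(idx, GenomicRange("chr1", 9, 10))) == [0]

    def test_query_spanning_all(self, small_table):
        idx = build_index(small_table)
        assert list(overlap_query(idx, GenomicRange("chr1", 0, 1000))) == [0, 1, 2]

    def test_unknown_chromosome_empty(self, small_table):
        idx = build_index(small_table)
        assert overlap_query(idx, GenomicRange("chrZ", 0, 100)).size == 0

    def test_result_sorted_by_start_end_index(self, rng):
        table = random_table(rng, 300, max_pos=5_000, max_len=400)
        idx = build_index(table)
        hits = overlap_query(idx, GenomicRange("chr1", 1_000, 3_000))
        keys = [(int(table.start[i]), int(table.end[i]), int(i)) for i in hits]
        assert keys == sorted(keys)

    def test_oracle_equivalence_randomized(self, rng):
        table = random_table(rng, 2_000, max_pos=50_000, max_len=1_000)
        idx = build_index(table)
        for _ in range(200):
            a = int(rng.integers(0, 50_000))
            b = a + int(rng.integers(1, 5_000))
            region = GenomicRange("chr1", a, b)
            assert list(overlap_query(idx, region)) == brute_overlap(table, region)

    @settings(max_examples=25, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_oracle_equivalence_property(self, rnd):
        rng = np.random.default_rng(rnd.randint(0, 2**32 - 1))
        table = random_table(rng, 80, max_pos=500, max_len=60)
        idx = build_index(table)
        a = int(rng.integers(0, 500))
        region = GenomicRange("chr1", a, a + int(rng.integers(1, 200)))
        assert list(overlap_query(idx, region)) == brute_overlap(table, region)


class TestSummarize:
    def test_single_point_bins(self):
        t = make_column_table(
            ["chr1", "chr1"], [10, 30], [11, 31], {"v": [2.0, 4.0]}
        )
        b = summarize(t, GenomicRange("chr1", 0, 100), n_bins=4, stat="mean")
        vals = b.values["v"]
        assert vals[0] == 2.0 and vals[1] == 4.0
        assert np.isnan(vals[2]) and np.isnan(vals[3])
        assert list(b.counts["v"]) == [1, 1, 0, 0]

    def test_constant_signal_every_bin_equals_constant(self):
        starts = np.arange(0, 1000, 10)
        t = make_column_table(
            ["chr1"] * 100, starts, starts + 10, {"v": [7.5] * 100}
        )
        b = summarize(t, GenomicRange("chr1", 0, 1000), n_bins=20)
        assert np.allclose(b.values["v"], 7.5)

    def test_default_is_2000_bins(self, fixture_source, whole_region):
        b = summarize(fixture_source.tables["signal"], whole_region)
        assert b.n_bins == 2000
        assert len(b.bin_starts) == 2000

    def test_bins_tile_region_contiguously(self):
        t = make_column_table(["chr1"], [0], [1], {"v": [1.0]})
        region = GenomicRange("chr1", 13, 1013)  # span 1000, 7 bins -> remainder
        b = summarize(t, region, n_bins=7)
        assert b.bin_starts[0] == region.start
        assert b.bin_ends[-1] == region.end
        assert list(b.bin_starts[1:]) == list(b.bin_ends[:-1])

    def test_n_bins_below_one_rejected(self, small_table):
        with pytest.raises(ValueError):
            summarize(small_table, GenomicRange("chr1", 0, 10), n_bins=0)

    def test_null_exactly_where_count_zero(self, rng):
        table = random_table(rng, 200, max_pos=10_000, max_len=5)
        for stat in ("mean", "min", "max", "sum", "count"):
            b = summarize(table, GenomicRange("chr1", 0, 20_000), 50, stat)
            assert np.array_equal(np.isnan(b.values["v"]), b.counts["v"] == 0)

    def test_one_bin_mean_equals_plain_mean_on_point_data(self, rng):
        starts = rng.integers(0, 10_000, size=500)
        vals = rng.normal(size=500)
        t = make_column_table(["chr1"] * 500, starts, starts + 1, {"v": vals})
        b = summarize(t, GenomicRange("chr1", 0, 10_000), n_bins=1)
        inside = starts < 10_000
        assert b.values["v"][0] == pytest.approx(vals[inside].mean())

    def test_count_stat_sums_to_incidences(self, rng):
        # point data never spans a bin boundary -> incidences == hits
        starts = rng.integers(0, 10_000, size=400)
        t = make_column_table(["chr1"] * 400, starts, starts + 1,
                              {"v": rng.normal(size=400)})
        region = GenomicRange("chr1", 0, 10_000)
        b = summarize(t, region, n_bins=100, stat="count")
        hits = overlap_query(build_index(t), region)
        assert np.nansum(b.values["v"]) == hits.size
        assert sum(b.counts["v"]) == hits.size

    def test_row_contributes_to_every_intersected_bin(self):
        # one row spanning bins 1-3 of [0,40)/4
        t = make_column_table(["chr1"], [12], [35], {"v": [6.0]})
        b = summarize(t, GenomicRange("chr1", 0, 40), n_bins=4, stat="mean")
        assert np.isnan(b.values["v"][0])
        assert list(b.values["v"][1:]) == [6.0, 6.0, 6.0]
        assert list(b.counts["v"]) == [0, 1, 1, 1]

    def test_brute_force_oracle_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 120))
            table = random_table(rng, n, max_pos=2_000, max_len=150)
            region = GenomicRange("chr1", int(rng.integers(0, 500)),
                                  int(rng.integers(1_000, 3_000)))
            n_bins = int(rng.integers(1, 20))
            stat = str(rng.choice(["mean", "min", "max", "sum", "count"]))
            b = summarize(table, region, n_bins, stat)
            exp_vals, exp_counts = brute_summarize(table, region, n_bins, stat, "v")
            assert list(b.counts["v"]) == exp_counts
            for got, want in zip(b.values["v"], exp_vals):
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want)

    def test_wmean_weights_by_overlap_length(self):
        # [0,30) v=3 and [20,40) v=9 in bin [0,40): wmean = (3*30+9*20)/50
        t = make_column_table(["chr1", "chr1"], [0, 20], [30, 40], {"v": [3.0, 9.0]})
        b = summarize(t, GenomicRange("chr1", 0, 40), n_bins=1, stat="wmean")
        assert b.values["v"][0] == pytest.approx((3 * 30 + 9 * 20) / 50)


class TestGroupOverlappingPoints:
    def test_width_one_collapses_everything(self, small_table):
        groups = group_overlapping_points(
            small_table, GenomicRange("chr1", 0, 100), 1
        )
        assert len(groups) == 1
        assert set(groups[0].rows) == {0, 1, 2}

    def test_wide_plot_one_group_per_row(self):
        t = make_column_table(
            ["chr1"] * 3, [0, 100, 200], [1, 101, 201], {"v": [1, 2, 3]}
        )
        groups = group_overlapping_points(t, GenomicRange("chr1", 0, 300), 300)
        assert len(groups) == 3

    def test_union_of_members_is_overlap_set(self, rng):
        table = random_table(rng, 400, max_pos=20_000)
        region = GenomicRange("chr1", 2_000, 15_000)
        groups = group_overlapping_points(table, region, 100)
        members = sorted(r for g in groups for r in g.rows)
        assert members == sorted(brute_overlap(table, region))
        assert len(members) == len(set(members))  # disjoint groups

    def test_group_count_bounded(self, rng):
        table = random_table(rng, 50, max_pos=1_000)
        region = GenomicRange("chr1", 0, 2_000)
        for width in (10, 100, 1_000):
            groups = group_overlapping_points(table, region, width)
            assert len(groups) <= min(table.row_count, width)

    def test_group_count_monotone_in_width_empirically(self, rng):
        table = random_table(rng, 600, max_pos=100_000)
        region = GenomicRange("chr1", 0, 101_000)
        counts = [
            len(group_overlapping_points(table, region, w))
            for w in (800, 400, 100, 10)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_representative_value_is_group_mean(self):
        t = make_column_table(
            ["chr1"] * 2, [10, 12], [11, 13], {"v": [2.0, 4.0]}
        )
        (g,) = group_overlapping_points(t, GenomicRange("chr1", 0, 1000), 1)
        assert g.values["v"] == 3.0
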