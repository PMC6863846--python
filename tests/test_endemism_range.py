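"""Range sizes, weighted endemism and endemics-vs-area."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from karstflora.endemism_range import (RangeSizeTable, extent_endemics,
                                       log_area_endemics, range_sizes,
                                       small_range_stats, we_randomization,
                                       weighted_endemism)
from karstflora.spatial_grid import KarstExtent
from tests.conftest import random_layout


class TestRangeSizes:
    def test_multiple_records_one_cell(self, grid50):
        df = pd.DataFrame({"accepted_name": "a", "x_km": [1.0, 2.0, 3.0],
                           "y_km": [1.0, 2.0, 3.0]})
        rt = range_sizes(df, grid50)
        assert rt["a"] == 1

    def test_distinct_cells_counted_once(self, grid50):
        df = pd.DataFrame({"accepted_name": "a",
                           "x_km": [1.0, 1.0, 1.0], "y_km": [1.0, 60.0, 2.0]})
        assert range_sizes(df, grid50)["a"] == 2

    def test_subset_monotonicity(self, grid50):
        df = random_layout(np.random.default_rng(0))
        inside = df["x_km"] < 120
        full = range_sizes(df, grid50)
        sub = range_sizes(df.loc[inside], grid50, extent_label="karst")
        for sp in sub.sizes.index:
            assert sub[sp] <= full[sp]


class TestWeightedEndemism:
    def test_single_species_single_cell(self, grid50):
        df = pd.DataFrame({"accepted_name": ["a"], "x_km": [1.0], "y_km": [1.0]})
        cells = weighted_endemism(df, range_sizes(df, grid50), grid50)
        assert cells.loc[(0, 0), "WE"] == 1.0
        assert cells.loc[(0, 0), "CWE"] == 1.0

    def test_closed_form_mixed_ranges(self, grid50):
        # one cell holding species with range sizes 1, 2 and 4
        rows = [("a", 1.0, 1.0), ("b", 2.0, 2.0), ("b", 60.0, 1.0),
                ("c", 3.0, 3.0), ("c", 60.0, 2.0), ("c", 1.0, 60.0),
                ("c", 60.0, 60.0)]
        df = pd.DataFrame(rows, columns=["accepted_name", "x_km", "y_km"])
        cells = weighted_endemism(df, range_sizes(df, grid50), grid50)
        assert cells.loc[(0, 0), "WE"] == pytest.approx(1 + 0.5 + 0.25)
        assert cells.loc[(0, 0), "CWE"] == pytest.approx(1.75 / 3)

    def test_we_sums_to_species_count_exactly(self, grid50):
        rng = np.random.default_rng(42)
        for _ in range(20):
            df = random_layout(rng, n_species=int(rng.integers(5, 60)))
            cells = weighted_endemism(df, range_sizes(df, grid50), grid50)
            assert cells["WE"].sum() == pytest.approx(
                df["accepted_name"].nunique(), abs=1e-9)

    def test_cwe_bounds(self, grid50):
        df = random_layout(np.random.default_rng(1))
        cells = weighted_endemism(df, range_sizes(df, grid50), grid50)
        assert ((cells["CWE"] > 0) & (cells["CWE"] <= 1)).all()

    def test_missing_species_named_in_error(self, grid50):
        df = pd.DataFrame({"accepted_name": ["a", "ghost"],
                           "x_km": [1.0, 2.0], "y_km": [1.0, 2.0]})
        rt = RangeSizeTable("study_area", pd.Series({"a": 1}))
        with pytest.raises(KeyError, match="ghost"):
            weighted_endemism(df, rt, grid50)


class TestWERandomization:
    def test_degenerate_pool_is_ns(self):
        cells = pd.DataFrame({"richness": [3], "WE": [3 * 0.5]})
        out = we_randomization(cells, [2, 2, 2, 2, 2], n_draws=100, seed=0)
        assert out["we_significance"].iloc[0] == "ns"

    def test_fixed_seed_identical_quantiles(self):
        cells = pd.DataFrame({"richness": [4, 7], "WE": [2.0, 3.0]})
        ranges = np.arange(1, 30)
        a = we_randomization(cells, ranges, n_draws=200, seed=3)
        b = we_randomization(cells, ranges, n_draws=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_richness_beyond_pool_rejected(self):
        cells = pd.DataFrame({"richness": [10], "WE": [1.0]})
        with pytest.raises(ValueError):
            we_randomization(cells, [1, 2, 3], n_draws=10)

    def test_extreme_cells_flagged(self):
        # pool mostly wide-ranged: a cell of only range-1 species beats
        # every plausible random draw
        wide_pool = np.array([1, 1, 1] + [50] * 200)
        out = we_randomization(pd.DataFrame({"richness": [3], "WE": [3.0]}),
                               wide_pool, n_draws=500, seed=1)
        assert out["we_significance"].iloc[0] == "higher"
        # pool mostly single-cell: a cell of only wide species falls
        # below every plausible random draw
        narrow_pool = np.array([1] * 200 + [50, 50, 50])
        out = we_randomization(pd.DataFrame({"richness": [3], "WE": [3 / 50]}),
                               narrow_pool, n_draws=500, seed=1)
        assert out["we_significance"].iloc[0] == "lower"


class TestSmallRange:
    def test_all_single_cell(self):
        rt = RangeSizeTable("x", pd.Series({"a": 1, "b": 1}))
        assert small_range_stats(rt) == (2, 1.0)

    def test_mixed(self):
        rt = RangeSizeTable("x", pd.Series({"a": 1, "b": 1, "c": 2, "d": 5}))
        assert small_range_stats(rt) == (2, 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            small_range_stats(RangeSizeTable("x", pd.Series(dtype=int)))

    def test_generator_calibration(self, small_pool, small_records, grid50):
        # the synthetic pool is built at single_cell_fraction 0.40; the
        # recorded footprint should put ~40% of species in a single cell
        rt = range_sizes(small_records, grid50)
        _, prop = small_range_stats(rt)
        assert prop == pytest.approx(0.40, abs=0.07)


class TestExtentEndemics:
    def test_all_inside_is_endemic(self, grid50):
        ext = KarstExtent("NBZ", box(0, 0, 100, 100))
        df = pd.DataFrame({"accepted_name": ["a", "a", "b"],
                           "x_km": [10.0, 20.0, 150.0], "y_km": [10.0, 20.0, 10.0]})
        endemics = extent_endemics(df, ext)
        assert endemics == {"a"}

    def test_one_outside_record_disqualifies(self, grid50):
        ext = KarstExtent("NBZ", box(0, 0, 100, 100))
        df = pd.DataFrame({"accepted_name": ["a", "a"],
                           "x_km": [10.0, 150.0], "y_km": [10.0, 10.0]})
        assert extent_endemics(df, ext) == set()

    def test_nested_extent_monotonicity(self):
        nbz = KarstExtent("NBZ", box(0, 0, 50, 50))
        bz5 = KarstExtent("BZ5", box(-5, -5, 55, 55))
        df = random_layout(np.random.default_rng(2), n_records=200)
        assert extent_endemics(df, nbz) <= extent_endemics(df, bz5)


class TestLogAreaEndemics:
    def test_reference_points(self):
        df = log_area_endemics([(260.0, 134), (318126.0, 468)])
        assert df["log10_area"].iloc[0] == pytest.approx(2.4150, abs=5e-5)
        assert df["log10_endemics"].iloc[0] == pytest.approx(2.1271, abs=5e-5)
        assert df["log10_area"].iloc[1] == pytest.approx(5.5026, abs=5e-5)
        assert df["log10_endemics"].iloc[1] == pytest.approx(2.6702, abs=5e-5)

    def test_single_point_no_regression(self):
        df = log_area_endemics([(100.0, 10)])
        assert len(df) == 1
        assert np.isnan(df["fitted"].iloc[0])

    def test_zero_count_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero endemic"):
            df = log_area_endemics([(100.0, 0), (10.0, 5), (1000.0, 50)])
        assert len(df) == 2

    def test_ols_line_through_exact_log_linear_points(self):
        df = log_area_endemics([(10.0, 10.0), (100.0, 100.0), (1000.0, 1000.0)])
        assert df.attrs["slope"] == pytest.approx(1.0)
        assert np.allclose(df["residual"], 0.0, atol=1e-12)
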