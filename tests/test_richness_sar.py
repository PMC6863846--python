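"""Richness, accumulation curves, power-law fits and resampling tests."""

import numpy as np
import pandas as pd
import pytest

from karstflora.richness_sar import (NullRichness, accumulation_curve,
                                     add_cell_indices, cell_richness,
                                     classify_against_quantiles,
                                     classify_outliers, effort_regression,
                                     exact_accumulation_mean, fit_arrhenius,
                                     null_richness, resample_extent_test)
from tests.conftest import random_layout


class TestCellRichness:
    def test_duplicates_do_not_inflate_richness(self, grid50):
        df = pd.DataFrame({"accepted_name": ["a", "a", "a"],
                           "x_km": [1.0, 2.0, 3.0], "y_km": [1.0, 1.0, 1.0]})
        out = cell_richness(df, grid50)
        assert out.loc[(0, 0), "richness"] == 1
        assert out.loc[(0, 0), "record_count"] == 3
        doubled = cell_richness(pd.concat([df, df]), grid50)
        assert doubled.loc[(0, 0), "richness"] == 1

    def test_empty_input_empty_output(self, grid50):
        out = cell_richness(pd.DataFrame(columns=["accepted_name", "x_km", "y_km"]),
                            grid50)
        assert len(out) == 0

    def test_richness_never_exceeds_record_count(self, grid50):
        df = random_layout(np.random.default_rng(1))
        out = cell_richness(df, grid50)
        assert (out["richness"] <= out["record_count"]).all()


class TestEffortRegression:
    def test_identity_when_every_record_is_new_species(self):
        cells = pd.DataFrame({"record_count": [1, 4, 9, 16, 25],
                              "richness": [1, 4, 9, 16, 25]})
        reg = effort_regression(cells)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-10)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_richness_gives_zero_slope(self):
        cells = pd.DataFrame({"record_count": [1, 4, 9, 16],
                              "richness": [4, 4, 4, 4]})
        assert effort_regression(cells).slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        # closed-form OLS via the normal equations on 5 fixed points
        cells = pd.DataFrame({"record_count": [1, 4, 9, 16, 36],
                              "richness": [1, 3, 5, 9, 20]})
        x = np.sqrt(cells["record_count"].to_numpy(float))
        y = np.sqrt(cells["richness"].to_numpy(float))
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (
            n * (x * x).sum() - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        reg = effort_regression(cells)
        assert reg.slope == pytest.approx(slope, abs=1e-12)
        assert reg.intercept == pytest.approx(intercept, abs=1e-12)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            effort_regression(pd.DataFrame({"record_count": [1, 2],
                                            "richness": [1, 2]}))


class TestAccumulationCurve:
    def test_single_shared_species_gives_flat_curve(self, grid50):
        df = pd.DataFrame({"accepted_name": "only",
                           "x_km": [10.0, 60.0, 110.0], "y_km": [10.0] * 3})
        curve = accumulation_curve(df, grid50, n_permutations=10, seed=0)
        np.testing.assert_allclose(curve.mean, 1.0)

    def test_terminal_mean_equals_pooled_richness(self, grid50):
        df = random_layout(np.random.default_rng(2))
        pooled = df["accepted_name"].nunique()
        for perms in (1, 5, 50):
            curve = accumulation_curve(df, grid50, n_permutations=perms, seed=3)
            assert curve.mean[-1] == pytest.approx(pooled)

    def test_mean_is_nondecreasing(self, grid50):
        df = random_layout(np.random.default_rng(3))
        curve = accumulation_curve(df, grid50, n_permutations=30, seed=1)
        assert np.all(np.diff(curve.mean) >= -1e-9)

    def test_exact_method_matches_hypergeometric_formula(self):
        # brute-force oracle: average over all C(N, n) subsets on a tiny grid
        from itertools import combinations

        rng = np.random.default_rng(5)
        inc = rng.random((5, 7)) < 0.4
        inc[0, 0] = True  # ensure at least one occupied cell
        exact = exact_accumulation_mean(inc)
        for n in range(1, 6):
            subsets = list(combinations(range(5), n))
            brute = np.mean([inc[list(s)].any(axis=0).sum() for s in subsets])
            assert exact[n - 1] == pytest.approx(brute, abs=1e-12)

    def test_invalid_permutation_count(self, grid50):
        df = random_layout(np.random.default_rng(2))
        with pytest.raises(ValueError):
            accumulation_curve(df, grid50, n_permutations=0)


class TestArrhenius:
    def test_exact_recovery_sqrt_law(self):
        fit = fit_arrhenius([1, 4, 9, 16], [10, 20, 30, 40])
        assert fit.k == pytest.approx(10.0, abs=1e-6)
        assert fit.z == pytest.approx(0.5, abs=1e-6)

    def test_exact_recovery_identity(self):
        fit = fit_arrhenius([1, 2, 3, 4], [1, 2, 3, 4])
        assert fit.k == pytest.approx(1.0, abs=1e-6)
        assert fit.z == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("k,z", [(0.5, 0.1), (3.0, 0.48), (10.0, 1.0),
                                     (2.0, 1.5)])
    def test_noise_free_recovery_across_parameter_grid(self, k, z):
        a = np.linspace(1, 50, 25)
        fit = fit_arrhenius(a, k * a**z)
        assert fit.k == pytest.approx(k, abs=1e-6)
        assert fit.z == pytest.approx(z, abs=1e-6)
        assert fit.rss < 1e-10

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            fit_arrhenius([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_arrhenius([1, 2], [1, 2])


class TestNullRichness:
    def test_degenerate_single_species(self, grid50, grid10):
        df = pd.DataFrame({"accepted_name": "only",
                           "record_id": [f"r{i}" for i in range(40)],
                           "x_km": np.linspace(1, 199, 40),
                           "y_km": np.linspace(1, 99, 40)})
        null = null_richness(df, grid50, grid10, n_draws=20, seed=1)
        assert np.nanmax(np.abs(null.expected - 1.0)) < 1e-6

    def test_fixed_seed_identical(self, grid50, grid10):
        df = random_layout(np.random.default_rng(7), n_records=600)
        df["record_id"] = [f"r{i}" for i in range(len(df))]
        a = null_richness(df, grid50, grid10, n_draws=15, seed=5)
        b = null_richness(df, grid50, grid10, n_draws=15, seed=5)
        np.testing.assert_array_equal(a.expected, b.expected)

    def test_invariant_to_record_order(self, grid50, grid10):
        df = random_layout(np.random.default_rng(8), n_records=600)
        df["record_id"] = [f"r{i}" for i in range(len(df))]
        shuffled = df.sample(frac=1.0, random_state=9)
        a = null_richness(df, grid50, grid10, n_draws=10, seed=2)
        b = null_richness(shuffled, grid50, grid10, n_draws=10, seed=2)
        np.testing.assert_allclose(a.expected, b.expected)

    def test_empty_extent_rejected(self, grid50, grid10):
        with pytest.raises(ValueError):
            null_richness(pd.DataFrame(columns=["accepted_name", "x_km", "y_km"]),
                          grid50, grid10)


class TestClassifyOutliers:
    def test_extremes_and_centre(self):
        null = NullRichness(
            cells=((0, 0),), expected=np.arange(10.0, 30.0).reshape(-1, 1),
            q25=np.array([14.75]), q75=np.array([24.25]),
            occupied_subcells=np.array([4.0]), z_values=np.zeros(20),
            k_values=np.ones(20), n_draws=20)
        assert classify_outliers({(0, 0): 5.0}, null) == {(0, 0): -1}
        assert classify_outliers({(0, 0): 50.0}, null) == {(0, 0): 2}
        assert classify_outliers({(0, 0): 19.5}, null) == {(0, 0): 1}

    def test_boundary_values_are_non_outliers(self):
        assert list(classify_against_quantiles([1.0, 2.0, 3.0], 1.0, 3.0)) == [1, 1, 1]

    def test_missing_null_warns_and_skips(self):
        null = NullRichness(cells=((0, 0),), expected=np.ones((5, 1)),
                            q25=np.array([1.0]), q75=np.array([1.0]),
                            occupied_subcells=np.array([1.0]),
                            z_values=np.zeros(5), k_values=np.ones(5), n_draws=5)
        with pytest.warns(UserWarning, match="skipped"):
            out = classify_outliers({(9, 9): 3.0}, null)
        assert out == {}


class TestResampleTest:
    def test_centred_case_gives_t_zero_p_one(self):
        # study pool of a single value: every replicate mean equals the
        # observed value, so the centred t is 0 and p is 1
        test = resample_extent_test([2.0, 2.0, 2.0], observed=2.0,
                                    sample_size=2, n_samples=10, seed=0)
        assert np.isnan(test.t) or test.t == pytest.approx(0.0, abs=1e-12)
        from scipy import stats

        t, p = stats.ttest_1samp(np.array([1.0, 2.0, 3.0]), 2.0)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_t_on_four_values(self):
        from scipy import stats

        reps = np.array([1.0, 2.0, 3.0, 4.0])
        t, _ = stats.ttest_1samp(reps, 0.0)
        sd = np.std(reps, ddof=1)
        assert t == pytest.approx(np.mean(reps) / (sd / 2), abs=1e-12)
        assert t == pytest.approx(3.872983346207417, abs=1e-9)

    def test_df_is_replicates_minus_one(self):
        study = np.random.default_rng(1).normal(size=50)
        test = resample_extent_test(study, study[:10], n_samples=200, seed=2)
        assert test.df == 199
        assert test.n_replicates == 200

    def test_sample_size_cannot_exceed_study(self):
        with pytest.raises(ValueError):
            resample_extent_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_custom_statistic(self):
        study = np.arange(20.0)
        test = resample_extent_test(study, study[:5], n_samples=50, seed=3,
                                    statistic=lambda v: float(np.median(
                                        np.asarray(v, dtype=float))))
        assert test.observed == 2.0
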