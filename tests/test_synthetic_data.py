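"""Synthetic landscape generators: determinism, calibration, contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from karstflora.cleaning import backbone_congruence
from karstflora.karst_validation import KARST_KEYWORDS, fold
from karstflora.synthetic_data import (LandscapeSpec, gen_backbones,
                                       gen_karst_polygons, gen_occurrences,
                                       gen_redlist, gen_species_pool,
                                       read_occurrences_csv,
                                       realized_single_cell_fraction,
                                       write_occurrences_csv)


class TestLandscapeSpec:
    @pytest.mark.parametrize("bad", [
        {"width_km": 80},
        {"n_species": 0},
        {"single_cell_fraction": 1.2},
        {"karst_fraction": 0.0},
        {"karst_fraction": 0.9},
        {"coord_error_fraction": -0.1},
        {"effort_bias": -1.0},
    ])
    def test_invalid_parameters_rejected_by_name(self, bad):
        with pytest.raises(ValueError, match=next(iter(bad))):
            LandscapeSpec(**bad)


class TestSpeciesPool:
    def test_single_cell_fraction_one_forces_small_radii(self):
        spec = LandscapeSpec(n_species=60, single_cell_fraction=1.0, seed=5)
        pool = gen_species_pool(spec)
        assert np.all(pool.radius_km < 25.0)
        assert realized_single_cell_fraction(pool) == 1.0

    def test_realized_fraction_tracks_target(self):
        fractions = [
            realized_single_cell_fraction(gen_species_pool(
                LandscapeSpec(n_species=200, single_cell_fraction=0.4, seed=s)))
            for s in range(60)
        ]
        assert all(abs(f - 0.4) <= 0.07 for f in fractions)
        assert abs(np.mean(fractions) - 0.4) < 0.02

    def test_deterministic_for_fixed_seed(self, small_spec):
        a = gen_species_pool(small_spec)
        b = gen_species_pool(small_spec)
        assert a.names == b.names
        np.testing.assert_array_equal(a.centre_x, b.centre_x)
        np.testing.assert_array_equal(a.radius_km, b.radius_km)
        np.testing.assert_array_equal(a.abundance, b.abundance)

    def test_abundances_sum_to_one_and_skewed(self, small_pool):
        assert small_pool.abundance.sum() == pytest.approx(1.0)
        assert np.all(small_pool.abundance > 0)
        # few common, many rare: mean far above median
        assert np.mean(small_pool.abundance) > 1.5 * np.median(small_pool.abundance)


class TestKarstPolygons:
    def test_area_fraction_near_target(self):
        spec = LandscapeSpec(karst_fraction=0.05, seed=9)
        karst = gen_karst_polygons(spec)
        ratio = karst.area_km2 / (spec.width_km * spec.height_km)
        assert 0.03 <= ratio <= 0.07

    def test_polygons_valid(self):
        karst = gen_karst_polygons(LandscapeSpec(seed=4))
        assert karst.geometry.is_valid

    def test_fixed_seed_identical(self):
        spec = LandscapeSpec(seed=12)
        assert gen_karst_polygons(spec).geometry.equals_exact(
            gen_karst_polygons(spec).geometry, 0)


class TestOccurrences:
    def test_zero_records_gives_empty_frame(self, small_pool, small_spec):
        spec = dataclasses.replace(small_spec, n_records=0)
        assert len(gen_occurrences(small_pool, spec)) == 0

    def test_zero_error_fraction_means_no_uncertainty(self, small_pool, small_spec):
        spec = dataclasses.replace(small_spec, coord_error_fraction=0.0, n_records=500)
        occ = gen_occurrences(small_pool, spec)
        assert (occ["coordinate_uncertainty_m"] == 0).all()

    def test_exact_error_count_and_jitter_bound(self, small_records):
        n = len(small_records)
        err = small_records["coordinate_uncertainty_m"] == 5000
        assert int(err.sum()) == round(0.5 * n)
        moved = np.hypot(small_records["x_km"] - small_records["true_x_km"],
                         small_records["y_km"] - small_records["true_y_km"])
        assert np.all(moved <= small_records["coordinate_uncertainty_m"] / 1000 + 1e-9)

    def test_records_inside_true_species_range(self, small_pool, small_records):
        idx = {n: i for i, n in enumerate(small_pool.names)}
        sp = small_records["verbatim_name"].map(idx).to_numpy()
        d = np.hypot(small_records["true_x_km"] - small_pool.centre_x[sp],
                     small_records["true_y_km"] - small_pool.centre_y[sp])
        assert np.all(d <= small_pool.radius_km[sp] + 1e-9)

    def test_uniform_sampling_when_bias_zero(self):
        spec = LandscapeSpec(width_km=200, height_km=200, n_species=1,
                             n_records=10_000, single_cell_fraction=0.0,
                             effort_bias=0.0, coord_error_fraction=0.0, seed=21)
        # one landscape-covering species so the range does not constrain cells
        pool = gen_species_pool(spec)
        pool = dataclasses.replace(
            pool, centre_x=np.array([100.0]), centre_y=np.array([100.0]),
            radius_km=np.array([300.0]))
        occ = gen_occurrences(pool, spec)
        # chi-square GOF against uniform over the 4 inner 100x100 quadrants
        inner = occ[(occ["x_km"].between(0, 200)) & (occ["y_km"].between(0, 200))]
        qx = (inner["x_km"] > 100).astype(int)
        qy = (inner["y_km"] > 100).astype(int)
        counts = np.bincount(qx * 2 + qy, minlength=4)
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.01

    def test_keywords_only_inside_karst(self, small_spec, small_pool, small_records):
        karst = gen_karst_polygons(small_spec)
        has_kw = small_records["habitat_notes"].map(
            lambda t: any(fold(k) in fold(t) for k in KARST_KEYWORDS))
        inside = karst.contains_points(small_records["true_x_km"].to_numpy(),
                                       small_records["true_y_km"].to_numpy())
        assert not (has_kw & ~pd.Series(inside)).any()
        assert has_kw.sum() > 0

    def test_csv_round_trip(self, small_records, tmp_path):
        path = tmp_path / "occ.csv"
        write_occurrences_csv(small_records, path)
        again = read_occurrences_csv(path)
        assert len(again) == len(small_records)
        assert list(again["record_id"]) == list(small_records["record_id"])
        np.testing.assert_allclose(again["decimal_longitude"],
                                   small_records["decimal_longitude"], rtol=1e-12)


class TestBackbones:
    def test_zero_synonym_fraction_only_notfound_differ(self, small_pool, small_spec):
        spec = dataclasses.replace(small_spec, synonym_fraction=0.0)
        a, b = gen_backbones(small_pool, spec)
        rep = backbone_congruence(list(small_pool.names), b)
        assert rep.synonymous == 0
        assert rep.not_found == round(0.05 * len(small_pool))
        assert rep.shared == len(small_pool) - rep.not_found

    def test_synonym_fraction_recovered_by_congruence(self):
        spec = LandscapeSpec(n_species=500, synonym_fraction=0.166, seed=8)
        pool = gen_species_pool(spec)
        _, b = gen_backbones(pool, spec)
        rep = backbone_congruence(list(pool.names), b)
        assert rep.synonymous_pct == pytest.approx(16.6, abs=1.0)

    def test_backbone_a_accepts_everything(self, small_pool, small_spec):
        a, _ = gen_backbones(small_pool, small_spec)
        assert all(a.status(n) == "accepted" for n in small_pool.names)

    def test_synonyms_resolve_to_accepted_names(self, small_pool, small_spec):
        _, b = gen_backbones(small_pool, small_spec)
        for name in small_pool.names:
            if b.status(name) == "synonym":
                target = b.resolve(name)
                assert b.status(target) == "accepted"


class TestRedlist:
    def test_zero_probs_empty_table(self, small_pool):
        assert gen_redlist(small_pool, {}, seed=1) == {}

    def test_all_lc(self, small_pool):
        rl = gen_redlist(small_pool, {"LC": 1.0}, seed=1)
        assert set(rl.values()) == {"LC"}
        assert len(rl) == len(small_pool)

    def test_binomial_category_count(self):
        spec = LandscapeSpec(n_species=1000, seed=3)
        pool = gen_species_pool(spec)
        rl = gen_redlist(pool, {"VU": 0.2}, seed=3)
        n_vu = sum(1 for c in rl.values() if c == "VU")
        assert abs(n_vu - 200) <= 25

    def test_invalid_probs_rejected(self, small_pool):
        with pytest.raises(ValueError):
            gen_redlist(small_pool, {"VU": 0.9, "LC": 0.9})
        with pytest.raises(ValueError):
            gen_redlist(small_pool, {"XX": 0.1})
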