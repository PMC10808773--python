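"""The synthetic-data generator: design constraints, marginal shapes,
and the moment oracles of the generative hierarchy."""

import numpy as np
import pandas as pd
import pytest

from pinebird import StudyDesign, TrueParameters
from pinebird.design import point_count_survey_area_km2, transect_area_m2
from pinebird.synth import (
    generate_covariates,
    generate_landscape,
    simulate_annotation_tallies,
    simulate_dataset,
    simulate_detections,
    simulate_spatial_effects,
    simulate_vocal_counts,
)


def test_survey_geometry_constants():
    assert point_count_survey_area_km2(0.1) == pytest.approx(0.0314, abs=5e-5)
    assert transect_area_m2() == 4000.0


class TestLandscape:
    def test_default_design_layout(self):
        sites = generate_landscape(StudyDesign(seed=4))
        assert len(sites) == 30
        sizes = sites.groupby("group_id").size()
        assert len(sizes) == 10
        assert sizes.between(2, 4).all()

    def test_minimum_separation_and_group_spread(self):
        design = StudyDesign(seed=11)
        sites = generate_landscape(design)
        xy = sites[["x_km", "y_km"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= design.min_site_separation_km
        for _, grp in sites.groupby("group_id"):
            g = grp[["x_km", "y_km"]].to_numpy()
            centroid = g.mean(axis=0)
            assert np.all(np.hypot(*(g - centroid).T) <= 2 * design.group_spread_km)

    def test_single_site_degenerate(self):
        sites = generate_landscape(
            StudyDesign(n_sites=1, n_groups=1, sites_per_group=(1, 1), seed=0)
        )
        assert len(sites) == 1

    def test_determinism(self):
        a = generate_landscape(StudyDesign(seed=5))
        b = generate_landscape(StudyDesign(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_separation_raises(self):
        with pytest.raises(RuntimeError, match="separation"):
            # a 0.1 km group radius caps pairwise distances at 0.2 km < 0.3 km
            generate_landscape(
                StudyDesign(group_spread_km=0.1, min_site_separation_km=0.3, seed=0)
            )


class TestCovariates:
    def test_bounds_and_site_level_constancy(self):
        design = StudyDesign(seed=2)
        sites = generate_landscape(design)
        cov = generate_covariates(sites, design, 2)
        assert cov["prop_infected"].between(0.13, 1.0).all()
        assert (cov["cone_density"] >= 0).all()
        # BA/DBH/TOTALBA constant across seasons, cone/infection vary
        per_site = cov.groupby("site_id")
        assert (per_site["live_ba"].nunique() == 1).all()
        assert (per_site["mean_dbh_cm"].nunique() == 1).all()
        assert (per_site["total_ba"].nunique() == 1).all()
        assert (per_site["cone_density"].nunique() > 1).mean() > 0.8
        assert (per_site["prop_infected"].nunique() > 1).mean() > 0.8

    def test_cone_density_is_right_skewed(self):
        design = StudyDesign(
            n_sites=4000, n_groups=1000, sites_per_group=(2, 4),
            landscape_extent_km=600, seed=3,
        )
        sites = generate_landscape(design)
        cov = generate_covariates(sites, design, 3)
        cone = cov["cone_density"]
        assert cone.median() < 0.5 * cone.mean()

    def test_standardized_copies(self):
        design = StudyDesign(seed=2)
        cov = generate_covariates(generate_landscape(design), design, 2)
        for col in ("cone_density_std", "mean_dbh_cm_std", "year_std"):
            assert abs(cov[col].mean()) < 1e-9
            assert cov[col].std(ddof=0) == pytest.approx(1.0)


class TestSpatialEffects:
    def test_single_site_variance(self):
        sites = pd.DataFrame({"site_id": [0], "x_km": [0.0], "y_km": [0.0], "group_id": [0]})
        draws = np.array(
            [simulate_spatial_effects(sites, 2.0, 1.0, seed)[0] for seed in range(4000)]
        )
        assert draws.mean() == pytest.approx(0.0, abs=0.08)
        assert draws.var() == pytest.approx(2.0, rel=0.1)

    def test_empirical_covariance_matches_kernel(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 5, (10, 2))
        sites = pd.DataFrame(
            {"site_id": range(10), "x_km": xy[:, 0], "y_km": xy[:, 1], "group_id": 0}
        )
        sigma_sq, phi = 1.5, 0.6
        draws = np.array(
            [simulate_spatial_effects(sites, sigma_sq, phi, s) for s in range(5000)]
        )
        emp = np.cov(draws.T)
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        expected = sigma_sq * np.exp(-phi * d)
        assert np.max(np.abs(emp - expected)) < 0.12

    def test_large_phi_gives_independence(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 5, (5, 2))
        sites = pd.DataFrame(
            {"site_id": range(5), "x_km": xy[:, 0], "y_km": xy[:, 1], "group_id": 0}
        )
        draws = np.array([simulate_spatial_effects(sites, 1.0, 500.0, s) for s in range(3000)])
        corr = np.corrcoef(draws.T)
        off = corr[np.triu_indices(5, 1)]
        assert np.max(np.abs(off)) < 0.06


class TestDetections:
    def _cov(self, design, seed=0):
        sites = generate_landscape(design)
        return sites, generate_covariates(sites, design, seed)

    def test_detection_shut_off(self):
        design = StudyDesign(seed=1)
        sites, cov = self._cov(design)
        truth = TrueParameters(alpha=(-40.0, 0, 0, 0, 0, 0))
        hist = simulate_detections(cov, np.zeros(30), truth, design, 1, sites=sites)
        assert hist.surveys["detected"].sum() == 0

    def test_saturated_occupancy_and_detection(self):
        design = StudyDesign(seed=1)
        sites, cov = self._cov(design)
        truth = TrueParameters(beta=(40.0, 0, 0, 0, 0, 0), alpha=(40.0, 0, 0, 0, 0, 0))
        hist = simulate_detections(cov, np.zeros(30), truth, design, 1, sites=sites)
        assert hist.z.min() == 1
        assert (hist.surveys["detected"] == 1).all()

    def test_no_detection_without_occupancy(self):
        # Eq-3 consistency: y = 0 wherever z = 0
        design = StudyDesign(visits_per_site_season=(3, 3), seed=9)
        sites, cov = self._cov(design, 9)
        truth = TrueParameters(alpha=(3.0, 0, 0, 0, 0, 0))
        hist = simulate_detections(cov, np.zeros(30), truth, design, 9, sites=sites)
        per_ss = hist.surveys.groupby(["site_id", "season"])["detected"].max()
        for (site, season), det in per_ss.items():
            if hist.z[site, season] == 0:
                assert det == 0

    def test_null_model_occupancy_rate(self):
        design = StudyDesign(n_sites=200, n_groups=50, landscape_extent_km=200, seed=3)
        sites, cov = self._cov(design, 3)
        truth = TrueParameters(beta=(0.0,) * 6)
        hist = simulate_detections(cov, np.zeros(200), truth, design, 3, sites=sites)
        assert hist.z.mean() == pytest.approx(0.5, abs=0.04)

    def test_visit_counts_within_design_range(self):
        design = StudyDesign(seed=5)  # 0-3 visits
        sites, cov = self._cov(design, 5)
        hist = simulate_detections(cov, np.zeros(30), TrueParameters(), design, 5, sites=sites)
        k = hist.surveys.groupby(["site_id", "season"]).size()
        assert k.max() <= 3
        assert len(k) < 90  # some site-seasons had zero visits


class TestVocalCounts:
    def test_constant_mean_when_effects_zero(self):
        design = StudyDesign(seed=2)
        sites = generate_landscape(design)
        cov = generate_covariates(sites, design, 2)
        truth = TrueParameters(
            glmm_fixed=(0.0,) * 7, glmm_group_sd=(0.0, 0.0, 0.0), kappa=2.0
        )
        voc = simulate_vocal_counts(cov, truth, design, 2, sites=sites)
        # mu = exp(0) = 1 for every day; NB mean 1, var 1 + 1/2
        assert voc["n_vocalizations"].mean() == pytest.approx(1.0, abs=0.05)
        assert voc["n_vocalizations"].var() == pytest.approx(1.5, rel=0.12)

    def test_poisson_limit(self):
        design = StudyDesign(seed=2)
        sites = generate_landscape(design)
        cov = generate_covariates(sites, design, 2)
        truth = TrueParameters(
            glmm_fixed=(1.0, 0, 0, 0, 0, 0, 0), glmm_group_sd=(0, 0, 0), kappa=1e7
        )
        voc = simulate_vocal_counts(cov, truth, design, 2, sites=sites)
        y = voc["n_vocalizations"]
        assert y.var() == pytest.approx(y.mean(), rel=0.08)

    def test_negative_quadratic_peaks_interior(self):
        design = StudyDesign(seed=4)
        sites = generate_landscape(design)
        cov = generate_covariates(sites, design, 4)
        truth = TrueParameters(
            glmm_fixed=(2.0, 0, 0, 0, 0, 0.0, -1.0), glmm_group_sd=(0, 0, 0), kappa=50.0
        )
        voc = simulate_vocal_counts(cov, truth, design, 4, sites=sites)
        by_day = voc.groupby("day_of_year")["n_vocalizations"].mean()
        days = by_day.index.to_numpy()
        peak_day = by_day.idxmax()
        assert days.min() < peak_day < days.max()
        # edges clearly below the peak
        assert by_day.iloc[:5].mean() < 0.5 * by_day.max()
        assert by_day.iloc[-5:].mean() < 0.5 * by_day.max()


class TestAnnotationTallies:
    def test_perfect_precision_means_no_false_positives(self):
        df = simulate_annotation_tallies(500, 0.7, 0.5, 1.0, 1)
        assert (df["fp"] == 0).all()

    def test_perfect_recall_means_no_false_negatives(self):
        df = simulate_annotation_tallies(500, 0.7, 1.0, 0.9, 1)
        assert (df["fn"] == 0).all()

    def test_pooled_recall_converges(self):
        df = simulate_annotation_tallies(10_000, 0.7, 0.48, 1.0, 3)
        pooled = df[["tp", "fn"]].sum()
        assert pooled["tp"] / (pooled["tp"] + pooled["fn"]) == pytest.approx(0.48, abs=0.01)

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError):
            simulate_annotation_tallies(10, 1.2, 0.5, 0.5, 0)


def test_full_bundle_determinism():
    a = simulate_dataset(StudyDesign(seed=21), TrueParameters(), seed=21)
    b = simulate_dataset(StudyDesign(seed=21), TrueParameters(), seed=21)
    pd.testing.assert_frame_equal(a.sites, b.sites)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    pd.testing.assert_frame_equal(a.surveys, b.surveys)
    pd.testing.assert_frame_equal(a.vocals, b.vocals)
    pd.testing.assert_frame_equal(a.annotations, b.annotations)
    np.testing.assert_array_equal(a.w, b.w)
    np.testing.assert_array_equal(a.z, b.z)
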