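"""The occupancy model: data assembly, sampler contracts, prediction."""

import numpy as np
import pandas as pd
import pytest

from pinebird import MCMCConfig, PriorSpec, StudyDesign, TrueParameters, fit_occupancy
from pinebird.occupancy import OccupancyModelData, effect_curve, predict_psi, summarize_psi
from pinebird.synth import inv_logit, simulate_dataset


def test_retained_draw_arithmetic():
    cfg = MCMCConfig()  # the study layout: 3 x 60,000 / 30,000 / 15
    assert cfg.n_retained == 2000
    assert MCMCConfig(n_iter=6000, burn_in=3000, thin=3).n_retained == 1000


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)


class TestDataAssembly:
    def test_shapes_and_join(self, dataset):
        data = OccupancyModelData.from_frames(
            dataset.sites, dataset.covariates, dataset.surveys
        )
        assert data.x_occ.shape == (90, 6)
        assert data.x_det.shape == (len(dataset.surveys), 6)
        assert data.ss_row.max() < 90
        assert data.n_sites == 30

    def test_unknown_site_season_raises(self, dataset):
        bad = dataset.surveys.copy()
        bad.loc[0, "season"] = 99
        with pytest.raises(ValueError, match="unknown site-season"):
            OccupancyModelData.from_frames(dataset.sites, dataset.covariates, bad)

    def test_collinear_covariates_warn(self, dataset):
        cov = dataset.covariates.copy()
        cov["live_ba_std"] = cov["mean_dbh_cm_std"] * 1.0000001
        with pytest.warns(UserWarning, match="0.7"):
            OccupancyModelData.from_frames(dataset.sites, cov, dataset.surveys)

    def test_nonbinary_detections_raise(self, dataset):
        bad = dataset.surveys.copy()
        bad.loc[0, "detected"] = 2
        with pytest.raises(ValueError, match="binary"):
            OccupancyModelData.from_frames(dataset.sites, dataset.covariates, bad)


class TestSampler:
    def test_draw_shapes_and_support(self, occ_fit):
        cfg = occ_fit.config
        assert occ_fit.draws.shape == (cfg.n_chains, cfg.n_retained, 14)
        sigma = occ_fit.stacked("sigma_sq")
        phi = occ_fit.stacked("phi")
        assert np.all(sigma > 0)
        assert np.all(phi >= occ_fit.priors.phi_lower)
        assert np.all(phi <= occ_fit.priors.phi_upper)
        # z respects the data: any detection forces occupancy
        any_det = occ_fit.data.any_detection
        assert np.all(occ_fit.z()[:, any_det] == 1)

    def test_all_detections_force_high_psi(self, dataset):
        surveys = dataset.surveys.copy()
        surveys["detected"] = 1
        data = OccupancyModelData.from_frames(dataset.sites, dataset.covariates, surveys)
        fit = fit_occupancy(
            data, config=MCMCConfig(n_chains=2, n_iter=800, burn_in=300, thin=1, seed=1)
        )
        psi = predict_psi(fit)
        assert psi.mean() > 0.85

    def test_near_zero_spatial_variance_matches_nonspatial_fit(self, dataset):
        data = OccupancyModelData.from_frames(
            dataset.sites, dataset.covariates, dataset.surveys
        )
        cfg = MCMCConfig(n_chains=2, n_iter=2400, burn_in=800, thin=2, seed=2)
        # inverse-Gamma(1e6, 1) pins sigma^2 near 1e-6: w is effectively 0
        pinned = fit_occupancy(
            data, priors=PriorSpec(sigma_sq_shape=1e6, sigma_sq_scale=1.0), config=cfg
        )
        flat = fit_occupancy(data, config=cfg, spatial=False)
        assert np.median(pinned.stacked("sigma_sq")) < 1e-5
        for j in range(12):
            a = pinned.draws[:, :, j].reshape(-1)
            b = flat.draws[:, :, j].reshape(-1)
            se = np.sqrt(a.var() / 50 + b.var() / 50)
            assert abs(a.mean() - b.mean()) < 4 * se + 0.05

    def test_deterministic_under_seed(self, dataset):
        data = OccupancyModelData.from_frames(
            dataset.sites, dataset.covariates, dataset.surveys
        )
        cfg = MCMCConfig(n_chains=1, n_iter=300, burn_in=100, thin=1, seed=42)
        a = fit_occupancy(data, config=cfg)
        b = fit_occupancy(data, config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestPrediction:
    def test_zero_coefficients_give_half(self, occ_fit):
        fit = occ_fit
        saved_draws, saved_w = fit.draws.copy(), fit.w_draws.copy()
        try:
            fit.draws = np.zeros_like(fit.draws)
            fit.w_draws = np.zeros_like(fit.w_draws)
            psi = predict_psi(fit)
            assert np.all(psi == 0.5)
        finally:
            fit.draws, fit.w_draws = saved_draws, saved_w

    def test_hand_oracle_three_draws(self, occ_fit):
        x = occ_fit.data.x_occ[:5]
        site = occ_fit.data.site_idx[:5]
        psi = predict_psi(occ_fit, x, site)
        beta = occ_fit.beta()
        w = occ_fit.w()
        for s in (0, 7, 23):
            for r in range(5):
                expected = 1.0 / (1.0 + np.exp(-(x[r] @ beta[s] + w[s, site[r]])))
                assert psi[s, r] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_positive_covariate(self, occ_fit):
        fit = occ_fit
        keep = fit.beta()[:, 2] > 0  # cone effect positive in these draws
        if keep.sum() == 0:
            pytest.skip("no positive-cone draws in this short chain")
        x_lo = np.zeros((1, 6)); x_lo[0, 0] = 1; x_lo[0, 2] = -1.0
        x_hi = np.zeros((1, 6)); x_hi[0, 0] = 1; x_hi[0, 2] = 1.0
        lo = predict_psi(fit, x_lo, None)[keep]
        hi = predict_psi(fit, x_hi, None)[keep]
        assert np.all(hi > lo)

    def test_unknown_site_raises(self, occ_fit):
        with pytest.raises(ValueError, match="site"):
            predict_psi(occ_fit, occ_fit.data.x_occ[:1], np.array([999]))

    def test_psi_summary_table(self, occ_fit):
        t = summarize_psi(occ_fit)
        assert len(t) == 90
        assert ((t["psi_mean"] >= t["psi_q2.5"]) & (t["psi_mean"] <= t["psi_q97.5"])).all()


class TestEffectCurve:
    def test_single_point_matches_prediction_at_mean(self, occ_fit):
        curve = effect_curve(occ_fit, "beta_cone", np.array([0.0]))
        x = np.zeros((1, 6)); x[0, 0] = 1.0
        psi = predict_psi(occ_fit, x, None)
        assert curve["psi_mean"].iloc[0] == pytest.approx(psi.mean(), abs=1e-12)

    def test_degenerate_draws_give_deterministic_curve(self, occ_fit):
        fit = occ_fit
        saved = fit.draws.copy()
        try:
            fixed = np.array([0.3, 0.0, 1.2, 0.0, 0.0, 0.0])
            fit.draws = np.tile(
                np.concatenate([fixed, np.zeros(8)]), (fit.draws.shape[0], fit.draws.shape[1], 1)
            )
            grid = np.linspace(-2, 2, 9)
            curve = effect_curve(fit, "beta_cone", grid)
            expected = inv_logit(0.3 + 1.2 * grid)
            np.testing.assert_allclose(curve["psi_mean"], expected, atol=1e-12)
            np.testing.assert_allclose(curve["psi_q2.5"], expected, atol=1e-12)
        finally:
            fit.draws = saved

    def test_empty_grid_and_unknown_covariate(self, occ_fit):
        with pytest.raises(ValueError):
            effect_curve(occ_fit, "beta_cone", np.array([]))
        with pytest.raises(ValueError):
            effect_curve(occ_fit, "nonesuch", np.array([0.0]))
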