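"""Fit statistics, posterior predictive checks, coverage, and MCMC
diagnostics against hand computations, closed forms and arviz."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pinebird.checking import (
    PPCResult,
    chi_squared_stat,
    coverage_rate_95,
    convergence_report,
    effective_sample_size,
    freeman_tukey,
    posterior_predictive_check_glmm,
    posterior_predictive_check_occupancy,
    probability_of_direction,
    rhat,
)


class TestFitStatistics:
    def test_freeman_tukey_hand_values(self):
        assert freeman_tukey([1, 2, 3], [1, 2, 3]) == 0.0
        assert freeman_tukey([4.0], [1.0]) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        obs, exp = rng.uniform(0, 10, 20), rng.uniform(0, 10, 20)
        by_hand = sum((np.sqrt(o) - np.sqrt(e)) ** 2 for o, e in zip(obs, exp))
        assert freeman_tukey(obs, exp) == pytest.approx(by_hand, rel=1e-12)

    def test_freeman_tukey_rejects_negatives(self):
        with pytest.raises(ValueError):
            freeman_tukey([-1.0], [1.0])

    def test_chi_squared_hand_values(self):
        assert chi_squared_stat([1, 2], [1, 2]) == 0.0
        assert chi_squared_stat([3.0], [1.0]) == pytest.approx(4.0)

    def test_chi_squared_floor_guards_zero_expectation(self):
        val = chi_squared_stat([1.0], [0.0])
        assert np.isfinite(val)
        assert val == pytest.approx(1.0 / 1e-6)

    @given(
        arrays(np.float64, 12, elements=st.floats(0, 100)),
        arrays(np.float64, 12, elements=st.floats(0, 100)),
    )
    @settings(max_examples=50, deadline=None)
    def test_statistics_nonnegative_and_zero_iff_equal(self, obs, exp):
        ft = freeman_tukey(obs, exp)
        c2 = chi_squared_stat(obs, exp)
        assert ft >= 0 and c2 >= 0
        if np.array_equal(obs, exp):
            assert ft == 0 and c2 == 0


class TestPPC:
    def test_tie_convention_counts_as_extreme(self):
        r = PPCResult("freeman_tukey", "site", np.ones(10), np.ones(10))
        assert r.bayesian_p == 1.0

    def test_complement_property(self):
        rng = np.random.default_rng(1)
        t_obs, t_rep = rng.normal(size=500), rng.normal(size=500)
        p = np.mean(t_rep >= t_obs)
        p_flip = np.mean(-t_rep >= -t_obs)
        ties = np.mean(t_rep == t_obs)
        assert p + p_flip == pytest.approx(1.0 + ties)

    def test_occupancy_ppc_contract(self, occ_fit):
        for grouping in ("site", "replicate"):
            r = posterior_predictive_check_occupancy(
                occ_fit, "freeman_tukey", grouping, seed=0, max_draws=200
            )
            assert 0.0 <= r.bayesian_p <= 1.0
            assert len(r.observed_stats) == len(r.replicated_stats) == 200

    def test_occupancy_ppc_unknown_grouping(self, occ_fit):
        with pytest.raises(ValueError, match="grouping"):
            posterior_predictive_check_occupancy(occ_fit, "freeman_tukey", "visitwise")

    def test_glmm_ppc_contract(self, glmm_fit):
        for grouping in ("none", "site"):
            r = posterior_predictive_check_glmm(
                glmm_fit, "chi_squared", grouping, seed=0, max_draws=100
            )
            assert 0.0 <= r.bayesian_p <= 1.0

    def test_glmm_ppc_unknown_statistic(self, glmm_fit):
        with pytest.raises(ValueError, match="statistic"):
            posterior_predictive_check_glmm(glmm_fit, "ks", "none")


class TestCoverageRate:
    def test_identical_replicates_cover_everything(self):
        obs = np.arange(10.0)
        rep = np.tile(obs, (50, 1))
        assert coverage_rate_95(obs, rep) == 1.0

    def test_distant_observations_cover_nothing(self):
        obs = np.full(10, 1000.0)
        rep = np.random.default_rng(0).normal(size=(50, 10))
        assert coverage_rate_95(obs, rep) == 0.0

    def test_too_few_draws_raise(self):
        with pytest.raises(ValueError, match="40"):
            coverage_rate_95(np.zeros(5), np.zeros((39, 5)))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        obs = rng.poisson(5, 30).astype(float)
        rep = rng.poisson(5, (100, 30)).astype(float)
        perm = rng.permutation(30)
        assert coverage_rate_95(obs, rep) == coverage_rate_95(obs[perm], rep[:, perm])


class TestRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((3, 4000))
        assert rhat(chains) < 1.02

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert rhat(chains) > 3.0

    def test_hand_computed_example(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        # split into 4 half-chains of length 2
        split = np.array([[1, 2], [3, 4], [2, 3], [4, 5.0]])
        w = split.var(axis=1, ddof=1).mean()
        b_over_n = split.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((2 - 1) / 2 * w + b_over_n) / w)
        assert rhat(chains) == pytest.approx(expected, rel=1e-12)

    def test_constant_chain_sentinel(self):
        assert rhat(np.ones((2, 10))) == np.inf

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        chains = np.cumsum(rng.standard_normal((4, 800)), axis=1) * 0.01 + rng.standard_normal((4, 800))
        ours = rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        # rank-normalized variant differs slightly; same pass/fail region
        assert ours == pytest.approx(theirs, abs=0.05)


class TestESS:
    def test_independent_draws(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((4, 2000))
        total = 4 * 2000
        assert effective_sample_size(chains) == pytest.approx(total, rel=0.15)

    def test_ar1_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(7)
        m, n = 4, 20_000
        chains = np.empty((m, n))
        for c in range(m):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0] / np.sqrt(1 - rho**2)
            for t in range(1, n):
                x[t] = rho * x[t - 1] + e[t]
            chains[c] = x
        expected = m * n * (1 - rho) / (1 + rho)
        assert effective_sample_size(chains) == pytest.approx(expected, rel=0.15)

    def test_constant_chain_sentinel(self):
        assert np.isnan(effective_sample_size(np.ones((2, 10))))

    def test_capped_at_total(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((2, 100))
        assert effective_sample_size(chains) <= 200

    def test_agrees_with_arviz_on_ar1(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        rho, m, n = 0.7, 4, 5000
        chains = np.empty((m, n))
        for c in range(m):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + e[t]
            chains[c] = x
        ours = effective_sample_size(chains)
        theirs = float(az.ess(az.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, rel=0.2)


class TestProbabilityOfDirection:
    def test_examples(self):
        assert probability_of_direction([1.0, 2.0, 3.0]) == 1.0
        assert probability_of_direction([-1.0, 1.0, 2.0, 3.0]) == 0.75
        rng = np.random.default_rng(10)
        assert probability_of_direction(rng.standard_normal(100_000)) == pytest.approx(0.5, abs=0.01)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            probability_of_direction([])


def test_convergence_report_structure(occ_fit):
    rep = convergence_report(occ_fit)
    assert set(rep.table.columns) == {"parameter", "rhat", "ess", "pass"}
    assert len(rep.table) == len(occ_fit.param_names)
    assert (rep.table["rhat"] >= 0.97).all()
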