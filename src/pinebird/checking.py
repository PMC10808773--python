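"""Goodness-of-fit and convergence machinery.

Posterior predictive checks with Freeman-Tukey and Chi-squared
discrepancies under two data groupings, Bayesian p-values (adequate fit
reads near .5; < .1 or > .9 flags misfit), the 95% coverage rate for
count data (target 0.95), split-chain Rhat, autocorrelation-based
effective sample size, and probability-of-direction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GLMMPosterior
from .occupancy import PosteriorDraws
from .synth import inv_logit

CHI2_FLOOR = 1e-6


def freeman_tukey(observed, expected) -> float:
    """Freeman-Tukey discrepancy sum((sqrt(obs) - sqrt(exp))^2)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(obs < 0) or np.any(exp < 0):
        raise ValueError("entries must be nonnegative")
    return float(((np.sqrt(obs) - np.sqrt(exp)) ** 2).sum())


def chi_squared_stat(observed, expected, floor: float = CHI2_FLOOR) -> float:
    """Chi-squared discrepancy sum((obs-exp)^2 / max(exp, floor))."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    return float(((obs - exp) ** 2 / np.maximum(exp, floor)).sum())


_STATS = {"freeman_tukey": freeman_tukey, "chi_squared": chi_squared_stat}


@dataclass
class PPCResult:
    """Observed vs replicated discrepancies across posterior draws."""

    statistic: str
    grouping: str
    observed_stats: np.ndarray
    replicated_stats: np.ndarray

    @property
    def bayesian_p(self) -> float:
        """Fraction of draws with replicated stat >= observed stat (ties count)."""
        return float(np.mean(self.replicated_stats >= self.observed_stats))


def _grouped_sums(values: np.ndarray, key: np.ndarray, n_groups: int) -> np.ndarray:
    """Row-wise grouped sums for a (draws, n_obs) matrix."""
    out = np.zeros((values.shape[0], n_groups))
    for g in range(n_groups):
        mask = key == g
        if mask.any():
            out[:, g] = values[:, mask].sum(axis=1)
    return out


def posterior_predictive_check_occupancy(
    draws: PosteriorDraws,
    statistic: str = "freeman_tukey",
    grouping: str = "site",
    seed: int = 0,
    max_draws: int | None = 1000,
) -> PPCResult:
    """PPC for the occupancy model.

    Per retained draw, a replicate detection history is simulated from
    the drawn (z, alpha); observed and replicate detections are grouped
    either by site (summing visits within each site-season) or by
    replicate (summing sites within each visit index) and compared to
    the model's expected counts with the chosen discrepancy.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if grouping not in ("site", "replicate"):
        raise ValueError(f"unknown grouping {grouping!r}")
    stat = _STATS[statistic]
    data = draws.data
    rng = np.random.default_rng(seed)

    alpha = draws.alpha()
    z = draws.z()
    total = alpha.shape[0]
    idx = np.arange(total)
    if max_draws is not None and total > max_draws:
        idx = rng.choice(total, size=max_draws, replace=False)
    alpha, z = alpha[idx], z[idx]

    p = inv_logit(alpha @ data.x_det.T)          # (S, n_vis)
    e = p * z[:, data.ss_row]                    # expected detection prob
    y_rep = (rng.random(e.shape) < e).astype(float)

    key = data.ss_row if grouping == "site" else data.visit_idx
    n_groups = int(key.max()) + 1 if len(key) else 0
    obs_g = _grouped_sums(np.broadcast_to(data.y.astype(float), e.shape), key, n_groups)
    exp_g = _grouped_sums(e, key, n_groups)
    rep_g = _grouped_sums(y_rep, key, n_groups)

    t_obs = np.array([stat(obs_g[s], exp_g[s]) for s in range(e.shape[0])])
    t_rep = np.array([stat(rep_g[s], exp_g[s]) for s in range(e.shape[0])])
    return PPCResult(statistic, grouping, t_obs, t_rep)


def posterior_predictive_check_glmm(
    posterior: GLMMPosterior,
    statistic: str = "freeman_tukey",
    grouping: str = "none",
    seed: int = 0,
    max_draws: int | None = 400,
) -> PPCResult:
    """PPC for the activity GLMM.

    ``grouping='none'`` compares raw daily counts with their expected
    values; ``grouping='site'`` first sums counts within each
    site-season (both variants are reported since either aggregation is
    defensible for daily count data).
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if grouping not in ("none", "site"):
        raise ValueError(f"unknown grouping {grouping!r}")
    stat = _STATS[statistic]
    data = posterior.data
    rng = np.random.default_rng(seed)

    total = posterior.fixed().shape[0]
    idx = np.arange(total)
    if max_draws is not None and total > max_draws:
        idx = rng.choice(total, size=max_draws, replace=False)
    mu = posterior.mu_draws(idx)                 # (S, n_obs)
    kap = posterior.kappa()[idx]
    y_rep = rng.negative_binomial(kap[:, None], kap[:, None] / (kap[:, None] + mu))

    if grouping == "site":
        key = (
            pd.Series(zip(data.site_id, data.season)).astype("category").cat.codes.to_numpy()
        )
        n_groups = int(key.max()) + 1
        obs = _grouped_sums(
            np.broadcast_to(data.y.astype(float), mu.shape), key, n_groups
        )
        exp = _grouped_sums(mu, key, n_groups)
        rep = _grouped_sums(y_rep.astype(float), key, n_groups)
    else:
        obs = np.broadcast_to(data.y.astype(float), mu.shape)
        exp = mu
        rep = y_rep.astype(float)

    t_obs = np.array([stat(obs[s], exp[s]) for s in range(mu.shape[0])])
    t_rep = np.array([stat(rep[s], exp[s]) for s in range(mu.shape[0])])
    return PPCResult(statistic, grouping, t_obs, t_rep)


def coverage_rate_95(observed, replicated) -> float:
    """Fraction of observations inside the central 95% interval of their
    model replicates (target 0.95 for a well-calibrated model)."""
    obs = np.asarray(observed, dtype=float)
    rep = np.asarray(replicated, dtype=float)
    if rep.ndim != 2 or rep.shape[1] != obs.shape[0]:
        raise ValueError("replicated must be (n_draws, n_obs)")
    if rep.shape[0] < 40:
        raise ValueError("need at least 40 replicate draws per observation")
    lo = np.quantile(rep, 0.025, axis=0)
    hi = np.quantile(rep, 0.975, axis=0)
    return float(np.mean((obs >= lo) & (obs <= hi)))


def _split_chains(chains: np.ndarray) -> np.ndarray:
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Returns inf as a sentinel when the within-chain variance is zero
    (constant chains), rather than raising.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    split = _split_chains(chains)
    m, n = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    if w == 0:
        return float("inf")
    b_over_n = means.var(ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def _autocov(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    padded = np.zeros(2 * n)
    padded[:n] = xc
    f = np.fft.rfft(padded)
    acov = np.fft.irfft(f * np.conjugate(f))[:n].real / n
    return acov


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based ESS over split chains.

    Combines chains per the between/within decomposition, truncates the
    autocorrelation sum with Geyer's initial positive-pair rule, and
    caps the result at the total draw count.  Constant chains return the
    NaN sentinel.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    split = _split_chains(chains)
    m, n = split.shape
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    if w == 0:
        return float("nan")
    b_over_n = split.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b_over_n

    acov = np.stack([_autocov(split[c]) for c in range(m)])
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_hat
    rho[0] = 1.0

    tau = 1.0
    t = 1
    prev_pair = np.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)  # enforce monotone decreasing pairs
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    ess = m * n / tau
    return float(min(ess, m * n))


def probability_of_direction(draws) -> float:
    """Posterior probability that the parameter is positive."""
    d = np.asarray(draws, dtype=float).reshape(-1)
    if d.size < 1:
        raise ValueError("need at least one draw")
    return float(np.mean(d > 0))


@dataclass
class ConvergenceReport:
    """Per-parameter Rhat/ESS with the study's pass thresholds.

    Pass rule: Rhat < 1.1 everywhere; ESS > 200 for intercepts and
    > 400 for every other parameter.
    """

    table: pd.DataFrame

    @property
    def all_pass(self) -> bool:
        return bool(self.table["pass"].all())


_INTERCEPTS = ("beta_intercept", "alpha_intercept", "glmm_intercept")


def convergence_report(
    posterior: PosteriorDraws | GLMMPosterior,
    rhat_threshold: float = 1.1,
    ess_intercept: float = 200.0,
    ess_other: float = 400.0,
) -> ConvergenceReport:
    rows = []
    for name in posterior.param_names:
        ch = posterior.chains(name)
        r = rhat(ch)
        e = effective_sample_size(ch)
        thresh = ess_intercept if name in _INTERCEPTS else ess_other
        ok = (r < rhat_threshold) and np.isfinite(e) and (e > thresh)
        rows.append({"parameter": name, "rhat": r, "ess": e, "pass": ok})
    return ConvergenceReport(table=pd.DataFrame(rows))
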