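"""Bayesian negative-binomial GLMM for daily vocalization activity.

Daily detected-vocalization counts per site/season/day are modelled as

    y_i ~ NB(mu_i, kappa),   Var(y_i) = mu_i + mu_i^2 / kappa
    log(mu_i) = x'_i beta + u0_{g(i)} + u1_{g(i)} date_i + u2_{g(i)} date_i^2

with fixed effects (intercept, cone density, mean live DBH, proportion
infected, year, date, date^2; all standardized), a random intercept and
random linear/quadratic date slopes across the ~10 spatial groups of
sites, and an overdispersion (size) parameter kappa.  Basal areas are
excluded from this model (collinear with DBH for the acoustic site set).

Counts are interpreted as *relative* vocalization activity: the model
does not correct for imperfect detection.

Sampling is adaptive Metropolis-within-Gibbs: coordinate random-walk
updates for fixed and group effects and for log(kappa), with conjugate
inverse-Gamma draws for the three random-effect variances.  Proposal
scales adapt toward a 44% acceptance rate during burn-in only, then
freeze, so the retained chain is a valid time-homogeneous sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .occupancy import MCMCConfig

FIXED_NAMES = (
    "glmm_intercept",
    "glmm_cone",
    "glmm_dbh",
    "glmm_infected",
    "glmm_year",
    "glmm_date",
    "glmm_date2",
)


def nb_mean_variance(mu, kappa: float):
    """Variance mu + mu^2/kappa of the NB(mu, size kappa) distribution."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be nonnegative")
    out = mu + mu**2 / kappa
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GLMMPriorSpec:
    """N(0, 2.72) on coefficients, Uniform(0.01, 100) on kappa,
    inverse-Gamma(0.1, 0.1) on each random-effect variance."""

    coef_var: float = 2.72
    kappa_lower: float = 0.01
    kappa_upper: float = 100.0
    re_var_shape: float = 0.1
    re_var_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.coef_var <= 0:
            raise ValueError("coef_var must be positive")
        if not (0 < self.kappa_lower < self.kappa_upper):
            raise ValueError("invalid kappa prior bounds")
        if self.re_var_shape <= 0 or self.re_var_scale <= 0:
            raise ValueError("inverse-Gamma hyperparameters must be positive")


@dataclass
class GLMMData:
    """Validated arrays for the daily-count model."""

    y: np.ndarray          # (n,) nonnegative integer counts
    x_fix: np.ndarray      # (n, 7) standardized fixed design
    group: np.ndarray      # (n,) group index 0..n_groups-1
    n_groups: int
    date_std: np.ndarray   # (n,) standardized date (column 5 of x_fix)
    date_scaler: tuple     # (mean, sd) of day_of_year
    site_id: np.ndarray
    season: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if self.group.min() < 0 or self.group.max() >= self.n_groups:
            raise ValueError("group indices out of range")
        counts = np.bincount(self.group, minlength=self.n_groups)
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0).tolist()
            raise ValueError(f"groups with zero observations: {empty}")

    @classmethod
    def from_frames(
        cls, vocals: pd.DataFrame, covariates: pd.DataFrame, sites: pd.DataFrame
    ) -> "GLMMData":
        """Join daily counts with stand covariates and site groups.

        Habitat covariates use the standardized columns of the
        covariates table; date is z-scored over the pooled vocal rows
        and squared after standardization.
        """
        cov = covariates.set_index(["site_id", "season"])
        voc = vocals.reset_index(drop=True)
        key = pd.MultiIndex.from_arrays([voc["site_id"], voc["season"]])
        missing = ~key.isin(cov.index)
        if missing.any():
            raise ValueError(f"{int(missing.sum())} vocal rows lack covariates")
        sub = cov.loc[key]
        group = sites.set_index("site_id")["group_id"].loc[voc["site_id"]].to_numpy(int)

        doy = voc["day_of_year"].to_numpy(dtype=float)
        dm, dsd = float(doy.mean()), float(doy.std())
        dsd = dsd if dsd > 0 else 1.0
        date_std = (doy - dm) / dsd
        x_fix = np.column_stack(
            [
                np.ones(len(voc)),
                sub["cone_density_std"].to_numpy(),
                sub["mean_dbh_cm_std"].to_numpy(),
                sub["prop_infected_std"].to_numpy(),
                sub["year_std"].to_numpy(),
                date_std,
                date_std**2,
            ]
        )
        return cls(
            y=voc["n_vocalizations"].to_numpy(dtype=np.int64),
            x_fix=x_fix,
            group=group,
            n_groups=int(sites["group_id"].max()) + 1,
            date_std=date_std,
            date_scaler=(dm, dsd),
            site_id=voc["site_id"].to_numpy(int),
            season=voc["season"].to_numpy(int),
        )


@njit(cache=True)
def _run_glmm_chain(
    y, X, group, n_groups, date, date2,
    uy_vals, uy_counts,
    n_iter, burn_in, thin, n_keep,
    coef_var, kappa_lo, kappa_hi, ig_a, ig_b,
    grp_offsets, grp_rows,
    seed,
):
    """Hierarchically centered Metropolis-within-Gibbs chain.

    The group effects are sampled on the centered scale v_c ~ N(mean_c,
    tau_c^2) where mean_c is the corresponding fixed effect (intercept,
    date, date^2); those three fixed effects then have exact Gaussian
    conditionals given the v's, which decouples them from the likelihood
    and removes the intercept/group-mean random-walk confounding.  The
    remaining fixed effects and kappa use adaptive random-walk steps.
    """
    np.random.seed(seed)
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = math.log(y.mean() + 0.01)
    # centered group effects: v0 ~ N(beta0, tau0^2), v1 ~ N(beta_date, .), ...
    v0 = np.full(n_groups, beta[0])
    v1 = np.zeros(n_groups)
    v2 = np.zeros(n_groups)
    tau2 = np.ones(3) * 0.5
    kappa = 1.0

    eta = np.empty(n)
    for i in range(n):
        eta[i] = v0[group[i]]

    mh_fixed = np.array([1, 2, 3, 4])  # cone, dbh, infected, year
    n_scales = mh_fixed.shape[0] + 3 * n_groups + 1
    scales = np.full(n_scales, 0.3)
    acc = np.zeros(n_scales)
    out = np.zeros((n_keep, k + 3 * n_groups + 3 + 1))
    keep = 0

    for it in range(n_iter):
        # non-centered fixed effects, coordinate-wise random walk
        for jj in range(mh_fixed.shape[0]):
            j = mh_fixed[jj]
            delta = scales[jj] * np.random.standard_normal()
            dl = 0.0
            for i in range(n):
                e_new = eta[i] + delta * X[i, j]
                dl += y[i] * (e_new - eta[i]) - (y[i] + kappa) * (
                    math.log(kappa + math.exp(e_new)) - math.log(kappa + math.exp(eta[i]))
                )
            bnew = beta[j] + delta
            dl += -0.5 * (bnew * bnew - beta[j] * beta[j]) / coef_var
            if math.log(np.random.random()) < dl:
                beta[j] = bnew
                for i in range(n):
                    eta[i] += delta * X[i, j]
                acc[jj] += 1.0

        # centered group effects, one group and effect type at a time
        for g in range(n_groups):
            rows = grp_rows[grp_offsets[g]:grp_offsets[g + 1]]
            for which in range(3):
                sidx = mh_fixed.shape[0] + which * n_groups + g
                delta = scales[sidx] * np.random.standard_normal()
                dl = 0.0
                for i in rows:
                    if which == 0:
                        step = delta
                    elif which == 1:
                        step = delta * date[i]
                    else:
                        step = delta * date2[i]
                    e_new = eta[i] + step
                    dl += y[i] * step - (y[i] + kappa) * (
                        math.log(kappa + math.exp(e_new)) - math.log(kappa + math.exp(eta[i]))
                    )
                if which == 0:
                    cur, mean_c = v0[g], beta[0]
                elif which == 1:
                    cur, mean_c = v1[g], beta[5]
                else:
                    cur, mean_c = v2[g], beta[6]
                vnew = cur + delta
                dl += -0.5 * ((vnew - mean_c) ** 2 - (cur - mean_c) ** 2) / tau2[which]
                if math.log(np.random.random()) < dl:
                    for i in rows:
                        if which == 0:
                            eta[i] += delta
                        elif which == 1:
                            eta[i] += delta * date[i]
                        else:
                            eta[i] += delta * date2[i]
                    if which == 0:
                        v0[g] = vnew
                    elif which == 1:
                        v1[g] = vnew
                    else:
                        v2[g] = vnew
                    acc[sidx] += 1.0

        # centered fixed effects: exact Gaussian conditionals given the v's
        for which in range(3):
            if which == 0:
                vsum = v0.sum()
                bidx = 0
            elif which == 1:
                vsum = v1.sum()
                bidx = 5
            else:
                vsum = v2.sum()
                bidx = 6
            prec = n_groups / tau2[which] + 1.0 / coef_var
            mean = (vsum / tau2[which]) / prec
            beta[bidx] = mean + np.random.standard_normal() / math.sqrt(prec)

        # random-effect variances: conjugate inverse-Gamma
        ss0 = 0.0
        ss1 = 0.0
        ss2 = 0.0
        for g in range(n_groups):
            ss0 += (v0[g] - beta[0]) ** 2
            ss1 += (v1[g] - beta[5]) ** 2
            ss2 += (v2[g] - beta[6]) ** 2
        tau2[0] = (ig_b + 0.5 * ss0) / np.random.gamma(ig_a + 0.5 * n_groups, 1.0)
        tau2[1] = (ig_b + 0.5 * ss1) / np.random.gamma(ig_a + 0.5 * n_groups, 1.0)
        tau2[2] = (ig_b + 0.5 * ss2) / np.random.gamma(ig_a + 0.5 * n_groups, 1.0)

        # kappa: random walk on log scale, uniform prior on kappa
        kidx = n_scales - 1
        lk_new = math.log(kappa) + scales[kidx] * np.random.standard_normal()
        k_new = math.exp(lk_new)
        if kappa_lo < k_new < kappa_hi:
            dl = 0.0
            for u in range(uy_vals.shape[0]):
                dl += uy_counts[u] * (
                    math.lgamma(uy_vals[u] + k_new) - math.lgamma(uy_vals[u] + kappa)
                )
            dl += -n * (math.lgamma(k_new) - math.lgamma(kappa))
            dl += n * (k_new * math.log(k_new) - kappa * math.log(kappa))
            for i in range(n):
                mu = math.exp(eta[i])
                dl += -(y[i] + k_new) * math.log(k_new + mu) + (y[i] + kappa) * math.log(kappa + mu)
            dl += lk_new - math.log(kappa)  # log-scale proposal Jacobian
            if math.log(np.random.random()) < dl:
                kappa = k_new
                acc[kidx] += 1.0

        # diminishing-free adaptation: burn-in only
        if it < burn_in and (it + 1) % 50 == 0:
            for s in range(n_scales):
                rate = acc[s] / 50.0
                scales[s] *= math.exp(0.3 * (rate - 0.44))
                acc[s] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0 and keep < n_keep:
            pos = 0
            for j in range(k):
                out[keep, pos] = beta[j]
                pos += 1
            # report zero-mean deviations, the conventional random-effect scale
            for g in range(n_groups):
                out[keep, pos] = v0[g] - beta[0]
                pos += 1
            for g in range(n_groups):
                out[keep, pos] = v1[g] - beta[5]
                pos += 1
            for g in range(n_groups):
                out[keep, pos] = v2[g] - beta[6]
                pos += 1
            out[keep, pos] = tau2[0]
            out[keep, pos + 1] = tau2[1]
            out[keep, pos + 2] = tau2[2]
            out[keep, pos + 3] = kappa
            keep += 1
    return out


@dataclass
class GLMMPosterior:
    """Retained draws of the activity GLMM, [chain, iteration, parameter]."""

    param_names: tuple
    draws: np.ndarray
    data: GLMMData
    config: MCMCConfig
    priors: GLMMPriorSpec

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.param_names.index(name)].reshape(-1)

    def chains(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.param_names.index(name)]

    def fixed(self) -> np.ndarray:
        """(n_draws, 7) pooled fixed-effect draws."""
        return self.draws[:, :, 0:7].reshape(-1, 7)

    def group_effects(self, which: str) -> np.ndarray:
        g = self.data.n_groups
        start = {"intercept": 7, "date": 7 + g, "date2": 7 + 2 * g}[which]
        return self.draws[:, :, start:start + g].reshape(-1, g)

    def kappa(self) -> np.ndarray:
        return self.draws[:, :, -1].reshape(-1)

    def mu_draws(self, draw_indices: np.ndarray | None = None) -> np.ndarray:
        """Expected counts per observation for (a subset of) pooled draws."""
        fx = self.fixed()
        u0 = self.group_effects("intercept")
        u1 = self.group_effects("date")
        u2 = self.group_effects("date2")
        if draw_indices is not None:
            fx, u0, u1, u2 = fx[draw_indices], u0[draw_indices], u1[draw_indices], u2[draw_indices]
        d = self.data
        eta = (
            fx @ d.x_fix.T
            + u0[:, d.group]
            + u1[:, d.group] * d.date_std[None, :]
            + u2[:, d.group] * (d.date_std**2)[None, :]
        )
        return np.exp(eta)


GLMM_CONFIG_DEFAULT = MCMCConfig(n_chains=3, n_iter=60_000, burn_in=30_000, thin=20)


def fit_activity_glmm(
    data: GLMMData,
    priors: GLMMPriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> GLMMPosterior:
    """Fit the NB activity GLMM by adaptive Metropolis-within-Gibbs."""
    priors = priors or GLMMPriorSpec()
    config = config or GLMM_CONFIG_DEFAULT

    order = np.argsort(data.group, kind="stable")
    grp_rows = order.astype(np.int64)
    counts = np.bincount(data.group, minlength=data.n_groups)
    grp_offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    uy_vals, uy_counts = np.unique(data.y, return_counts=True)

    g = data.n_groups
    names = (
        list(FIXED_NAMES)
        + [f"u_intercept_g{i}" for i in range(g)]
        + [f"u_date_g{i}" for i in range(g)]
        + [f"u_date2_g{i}" for i in range(g)]
        + ["tau_sq_intercept", "tau_sq_date", "tau_sq_date2", "kappa"]
    )
    n_keep = config.n_retained
    draws = np.zeros((config.n_chains, n_keep, len(names)))
    for chain in range(config.n_chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(100 + chain,)))
        )
        draws[chain] = _run_glmm_chain(
            data.y.astype(np.float64),
            np.ascontiguousarray(data.x_fix),
            data.group.astype(np.int64),
            g,
            np.ascontiguousarray(data.date_std),
            np.ascontiguousarray(data.date_std**2),
            uy_vals.astype(np.float64),
            uy_counts.astype(np.float64),
            config.n_iter,
            config.burn_in,
            config.thin,
            n_keep,
            priors.coef_var,
            priors.kappa_lower,
            priors.kappa_upper,
            priors.re_var_shape,
            priors.re_var_scale,
            grp_offsets,
            grp_rows,
            int(rng.integers(0, 2**31 - 1)),
        )
    return GLMMPosterior(
        param_names=tuple(names), draws=draws, data=data, config=config, priors=priors
    )


def predict_activity(
    posterior: GLMMPosterior, x_fix: np.ndarray, group: int
) -> np.ndarray:
    """Expected daily count draws exp(eta) for new standardized rows.

    ``x_fix`` rows carry (intercept, cone, dbh, infected, year, date,
    date^2) on the training scale; the group's random intercept and date
    slopes are applied.  Unknown groups raise.
    """
    x_fix = np.atleast_2d(np.asarray(x_fix, dtype=float))
    if x_fix.shape[1] != 7:
        raise ValueError("x_fix must have 7 columns")
    if not (0 <= group < posterior.data.n_groups):
        raise ValueError(f"unknown group {group}")
    fx = posterior.fixed()
    u0 = posterior.group_effects("intercept")[:, group]
    u1 = posterior.group_effects("date")[:, group]
    u2 = posterior.group_effects("date2")[:, group]
    eta = (
        fx @ x_fix.T
        + u0[:, None]
        + u1[:, None] * x_fix[None, :, 5].reshape(1, -1)
        + u2[:, None] * x_fix[None, :, 6].reshape(1, -1)
    )
    return np.exp(eta)
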