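"""Bayesian spatially explicit multi-season occupancy model.

Hierarchy (site j, season t, visit k):

    z_{j,t}   ~ Bernoulli(psi_{j,t})
    logit(psi_{j,t}) = x'_{j,t} beta + w_j
    y_{j,t,k} ~ Bernoulli(p_{j,t,k} * z_{j,t})
    logit(p_{j,t,k}) = v'_{j,t,k} alpha

with occupancy covariates (intercept, year, cone density, live basal
area, mean live DBH, proportion infected), detection covariates
(intercept, date, date^2, wind, total basal area, year), and a
site-level spatial random effect w from an NNGP with exponential
correlation (15 neighbors).

The sampler is a Gibbs scheme: latent z from its Bernoulli full
conditional, beta/alpha via Polya-Gamma augmentation (exact conjugate
Gaussian updates on the logit scale), w via sequential NNGP full
conditionals, sigma^2 from its conjugate inverse-Gamma conditional, and
phi by Metropolis on its uniform prior support.  Zero-visit
site-seasons contribute through the occupancy layer only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pg
from .nngp import (
    NNGPStructure,
    _gibbs_update_w,
    _nngp_quad_and_logdet,
    build_nngp,
    nngp_factors,
    phi_prior_bounds,
)
from .synth import inv_logit

OCC_DESIGN_COLUMNS = (
    "beta_intercept",
    "beta_year",
    "beta_cone",
    "beta_live_ba",
    "beta_dbh",
    "beta_infected",
)
DET_DESIGN_COLUMNS = (
    "alpha_intercept",
    "alpha_date",
    "alpha_date2",
    "alpha_wind",
    "alpha_total_ba",
    "alpha_year",
)


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the occupancy model.

    Vague Gaussian N(0, 2.72) on every logit-scale coefficient,
    inverse-Gamma(2, 1) on the spatial variance, and an informative
    uniform on the spatial decay phi whose default support maps the
    effective spatial range onto [4.36 km, 84.31 km] (core-use-area
    diameter of tagged birds up to the maximum inter-site distance).
    """

    coef_mean: float = 0.0
    coef_var: float = 2.72
    sigma_sq_shape: float = 2.0
    sigma_sq_scale: float = 1.0
    phi_lower: float = phi_prior_bounds(4.36, 84.31)[0]
    phi_upper: float = phi_prior_bounds(4.36, 84.31)[1]

    def __post_init__(self) -> None:
        if self.coef_var <= 0:
            raise ValueError("coef_var must be positive")
        if not (0 < self.phi_lower < self.phi_upper):
            raise ValueError("need 0 < phi_lower < phi_upper")
        if self.sigma_sq_shape <= 0 or self.sigma_sq_scale <= 0:
            raise ValueError("inverse-Gamma hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout; the study configuration is 3 x 60,000 / 30,000 / 15."""

    n_chains: int = 3
    n_iter: int = 60_000
    burn_in: int = 30_000
    thin: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: (n_iter - burn_in) // thin."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class OccupancyModelData:
    """Validated flat arrays for the ragged detection histories."""

    x_occ: np.ndarray        # (n_ss, 6) standardized occupancy design
    site_idx: np.ndarray     # (n_ss,) original site index per site-season
    season_idx: np.ndarray   # (n_ss,)
    x_det: np.ndarray        # (n_vis, 6) standardized detection design
    ss_row: np.ndarray       # (n_vis,) row of x_occ each visit belongs to
    visit_idx: np.ndarray    # (n_vis,)
    y: np.ndarray            # (n_vis,) binary detections
    coords: np.ndarray       # (n_sites, 2) km
    det_scaler: dict         # mean/sd used for detection covariates
    occ_cov_names: tuple = OCC_DESIGN_COLUMNS
    det_cov_names: tuple = DET_DESIGN_COLUMNS

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def n_site_seasons(self) -> int:
        return self.x_occ.shape[0]

    @property
    def any_detection(self) -> np.ndarray:
        out = np.zeros(self.n_site_seasons, dtype=bool)
        np.logical_or.at(out, self.ss_row, self.y.astype(bool))
        return out

    @classmethod
    def from_frames(
        cls,
        sites: pd.DataFrame,
        covariates: pd.DataFrame,
        surveys: pd.DataFrame,
    ) -> "OccupancyModelData":
        """Assemble design matrices from the CSV-schema frames.

        Occupancy covariates use the standardized columns stored in the
        covariates table (one scaling shared with the generator);
        detection covariates are z-scored over the survey rows here and
        the scaler retained.
        """
        sites = sites.sort_values("site_id").reset_index(drop=True)
        if not np.array_equal(sites["site_id"].to_numpy(), np.arange(len(sites))):
            raise ValueError("site_id must be 0..n_sites-1")
        cov = covariates.sort_values(["season", "site_id"]).reset_index(drop=True)
        n, n_seasons = len(sites), cov["season"].nunique()
        if len(cov) != n * n_seasons:
            raise ValueError("covariates must contain every site x season")

        x_occ = np.column_stack(
            [
                np.ones(len(cov)),
                cov["year_std"],
                cov["cone_density_std"],
                cov["live_ba_std"],
                cov["mean_dbh_cm_std"],
                cov["prop_infected_std"],
            ]
        ).astype(float)
        corr = np.corrcoef(x_occ[:, 1:], rowvar=False)
        hi = np.abs(corr[np.triu_indices_from(corr, 1)]) >= 0.7
        if np.any(hi):
            warnings.warn(
                "occupancy covariates with pairwise |r| >= 0.7 detected", stacklevel=2
            )

        ss_of = {
            (int(r.site_id), int(r.season)): i
            for i, r in enumerate(cov[["site_id", "season"]].itertuples(index=False))
        }
        sv = surveys.reset_index(drop=True)
        try:
            ss_row = np.array(
                [ss_of[(int(s), int(t))] for s, t in zip(sv["site_id"], sv["season"])]
            )
        except KeyError as err:
            raise ValueError(f"survey row references unknown site-season {err}") from err

        total_ba = cov["total_ba"].to_numpy()[ss_row] if len(sv) else np.zeros(0)
        year = cov["year"].to_numpy()[ss_row] if len(sv) else np.zeros(0)

        def _std(v: np.ndarray) -> tuple[np.ndarray, float, float]:
            m, s = float(np.mean(v)), float(np.std(v))
            if s == 0:
                return np.zeros_like(v, dtype=float), m, 1.0
            return (v - m) / s, m, s

        doy = sv["day_of_year"].to_numpy(dtype=float)
        wind = sv["wind"].to_numpy(dtype=float)
        date_std, dm, ds = _std(doy)
        wind_std, wm, ws = _std(wind)
        tba_std, tm, ts = _std(total_ba)
        yr_std, ym, ys = _std(year)
        x_det = np.column_stack(
            [np.ones(len(sv)), date_std, date_std**2, wind_std, tba_std, yr_std]
        ).astype(float)
        y = sv["detected"].to_numpy(dtype=int)
        if np.any((y != 0) & (y != 1)):
            raise ValueError("detected must be binary")

        return cls(
            x_occ=x_occ,
            site_idx=cov["site_id"].to_numpy(dtype=int),
            season_idx=cov["season"].to_numpy(dtype=int),
            x_det=x_det,
            ss_row=ss_row,
            visit_idx=sv["visit"].to_numpy(dtype=int) if len(sv) else np.zeros(0, int),
            y=y,
            coords=sites[["x_km", "y_km"]].to_numpy(dtype=float),
            det_scaler={
                "date": (dm, ds),
                "wind": (wm, ws),
                "total_ba": (tm, ts),
                "year": (ym, ys),
            },
        )


PARAM_NAMES = tuple(OCC_DESIGN_COLUMNS) + tuple(DET_DESIGN_COLUMNS) + ("sigma_sq", "phi")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: [chain, iteration, parameter] plus w and z."""

    param_names: tuple
    draws: np.ndarray        # (n_chains, n_keep, n_params)
    w_draws: np.ndarray      # (n_chains, n_keep, n_sites)
    z_draws: np.ndarray      # (n_chains, n_keep, n_ss), int8
    data: OccupancyModelData
    config: MCMCConfig
    priors: PriorSpec

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled for one named parameter."""
        i = self.param_names.index(name)
        return self.draws[:, :, i].reshape(-1)

    def chains(self, name: str) -> np.ndarray:
        """(n_chains, n_keep) matrix for one named parameter."""
        i = self.param_names.index(name)
        return self.draws[:, :, i]

    @property
    def n_total_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def beta(self) -> np.ndarray:
        return self.draws[:, :, 0:6].reshape(-1, 6)

    def alpha(self) -> np.ndarray:
        return self.draws[:, :, 6:12].reshape(-1, 6)

    def w(self) -> np.ndarray:
        return self.w_draws.reshape(-1, self.w_draws.shape[2])

    def z(self) -> np.ndarray:
        return self.z_draws.reshape(-1, self.z_draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long (chain, iteration, parameter, value) layout."""
        nc, nk, npar = self.draws.shape
        recs = []
        names = list(self.param_names) + [f"w_site{j}" for j in range(self.w_draws.shape[2])]
        flat = np.concatenate([self.draws, self.w_draws], axis=2)
        for c in range(nc):
            for i, name in enumerate(names):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(nk),
                            "parameter": name,
                            "value": flat[c, :, i],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


def _sample_gaussian_coefs(
    X: np.ndarray, omega: np.ndarray, kappa: np.ndarray, prior_prec: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from N(V X'kappa, V), V = (X'Omega X + prior_prec I)^-1."""
    k = X.shape[1]
    prec = X.T @ (X * omega[:, None]) + prior_prec * np.eye(k)
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, X.T @ kappa)
    return mean + np.linalg.solve(chol.T, rng.standard_normal(k))


def fit_occupancy(
    data: OccupancyModelData,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    spatial: bool = True,
    n_neighbors: int = 15,
) -> PosteriorDraws:
    """Fit the model by Polya-Gamma Gibbs with NNGP spatial effects.

    With ``spatial=False`` the spatial effect is pinned at zero and
    sigma^2/phi are not updated (nested non-spatial model, used for
    oracle comparisons).  Non-convergence is reported via diagnostics,
    never raised.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    if data.x_occ.shape[1] != 6 or data.x_det.shape[1] != 6:
        raise ValueError("design matrices must have 6 columns each")
    if len(data.ss_row) and data.ss_row.max() >= data.n_site_seasons:
        raise ValueError("visit rows reference missing site-seasons")

    structure = build_nngp(data.coords, n_neighbors=n_neighbors)
    ord_of_site = np.empty(data.n_sites, dtype=int)
    ord_of_site[structure.order] = np.arange(data.n_sites)
    site_ord_of_ss = ord_of_site[data.site_idx]  # ordered site per ss row

    n_keep = config.n_retained
    n_params = len(PARAM_NAMES)
    draws = np.zeros((config.n_chains, n_keep, n_params))
    w_draws = np.zeros((config.n_chains, n_keep, data.n_sites))
    z_draws = np.zeros((config.n_chains, n_keep, data.n_site_seasons), dtype=np.int8)

    any_det = data.any_detection
    prior_prec = 1.0 / priors.coef_var
    n_ss = data.n_site_seasons
    n_vis = len(data.y)

    for chain in range(config.n_chains):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(chain,)))
        )
        pg.seed_pg(int(rng.integers(0, 2**31 - 1)))

        beta = np.zeros(6)
        alpha = np.zeros(6)
        w = np.zeros(data.n_sites)
        w_ord = np.zeros(data.n_sites)
        sigma_sq = 1.0
        phi = 0.5 * (priors.phi_lower + priors.phi_upper)
        b_fac, f_fac = nngp_factors(structure, phi)
        z = np.where(any_det, 1, (rng.random(n_ss) < 0.5).astype(int))
        phi_step = 0.2 * (priors.phi_upper - priors.phi_lower)
        phi_acc = 0

        keep = 0
        for it in range(config.n_iter):
            # --- beta | z, w (Polya-Gamma)
            eta_occ = data.x_occ @ beta + w[data.site_idx]
            omega = pg.draw_pg1(eta_occ)
            kappa_vec = (z - 0.5) - omega * w[data.site_idx]
            beta = _sample_gaussian_coefs(data.x_occ, omega, kappa_vec, prior_prec, rng)

            # --- alpha | z, y: only occupied site-seasons carry detection info
            occ_rows = z[data.ss_row] == 1 if n_vis else np.zeros(0, dtype=bool)
            if n_vis and occ_rows.any():
                Xd = data.x_det[occ_rows]
                omega_d = pg.draw_pg1(Xd @ alpha)
                alpha = _sample_gaussian_coefs(
                    Xd, omega_d, data.y[occ_rows] - 0.5, prior_prec, rng
                )
            else:
                alpha = rng.normal(0.0, np.sqrt(priors.coef_var), size=6)

            if spatial:
                # --- w | beta, z, omega: sequential NNGP full conditionals
                xb = data.x_occ @ beta
                lik_prec = np.bincount(site_ord_of_ss, weights=omega, minlength=data.n_sites)
                lik_lin = np.bincount(
                    site_ord_of_ss, weights=(z - 0.5) - omega * xb, minlength=data.n_sites
                )
                w_ord = w[structure.order].copy()
                _gibbs_update_w(
                    w_ord, sigma_sq, structure.nbr_idx, structure.nbr_count,
                    b_fac, f_fac, structure.rev_idx, structure.rev_pos,
                    structure.rev_count, lik_prec, lik_lin,
                )
                w[structure.order] = w_ord

                # --- sigma^2 | w, phi: conjugate inverse-Gamma
                quad, logdet = _nngp_quad_and_logdet(
                    w_ord, structure.nbr_idx, structure.nbr_count, b_fac, f_fac
                )
                sigma_sq = (priors.sigma_sq_scale + 0.5 * quad) / rng.gamma(
                    priors.sigma_sq_shape + 0.5 * data.n_sites
                )

                # --- phi | w, sigma^2: Metropolis on the uniform support
                phi_prop = phi + phi_step * rng.standard_normal()
                if priors.phi_lower < phi_prop < priors.phi_upper:
                    b_prop, f_prop = nngp_factors(structure, phi_prop)
                    quad_p, logdet_p = _nngp_quad_and_logdet(
                        w_ord, structure.nbr_idx, structure.nbr_count, b_prop, f_prop
                    )
                    log_ratio = -0.5 * (logdet_p - logdet) - 0.5 * (quad_p - quad) / sigma_sq
                    if np.log(rng.random()) < log_ratio:
                        phi, b_fac, f_fac = phi_prop, b_prop, f_prop
                        phi_acc += 1
                if it < config.burn_in and (it + 1) % 100 == 0:
                    rate = phi_acc / 100.0
                    phi_step *= np.exp(0.3 * (rate - 0.44))
                    phi_step = min(phi_step, priors.phi_upper - priors.phi_lower)
                    phi_acc = 0

            # --- z | everything: Bernoulli full conditional
            psi = inv_logit(data.x_occ @ beta + w[data.site_idx])
            if n_vis:
                p_det = inv_logit(data.x_det @ alpha)
                log_q0 = np.bincount(
                    data.ss_row, weights=np.log1p(-p_det), minlength=n_ss
                )
            else:
                log_q0 = np.zeros(n_ss)
            p1 = psi * np.exp(log_q0)
            pr_z1 = p1 / (p1 + (1.0 - psi))
            z = (rng.random(n_ss) < pr_z1).astype(int)
            z[any_det] = 1

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and keep < n_keep:
                draws[chain, keep, 0:6] = beta
                draws[chain, keep, 6:12] = alpha
                draws[chain, keep, 12] = sigma_sq
                draws[chain, keep, 13] = phi
                w_draws[chain, keep] = w
                z_draws[chain, keep] = z
                keep += 1

    return PosteriorDraws(
        param_names=PARAM_NAMES,
        draws=draws,
        w_draws=w_draws,
        z_draws=z_draws,
        data=data,
        config=config,
        priors=priors,
    )


def predict_psi(
    draws: PosteriorDraws,
    x_occ: np.ndarray | None = None,
    site_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw occupancy probabilities, shape (n_draws, n_site_seasons).

    Defaults to the training site-seasons.  For custom covariate rows,
    ``x_occ`` must be on the training standardized scale and
    ``site_idx`` must reference fitted sites (kriging to new sites is
    out of scope: unknown sites raise).
    """
    if x_occ is None:
        x_occ = draws.data.x_occ
        site_idx = draws.data.site_idx
    x_occ = np.atleast_2d(np.asarray(x_occ, dtype=float))
    beta = draws.beta()
    eta = beta @ x_occ.T
    if site_idx is not None:
        site_idx = np.asarray(site_idx, dtype=int)
        if site_idx.min() < 0 or site_idx.max() >= draws.data.n_sites:
            raise ValueError("site_idx references a site with no fitted spatial effect")
        eta = eta + draws.w()[:, site_idx]
    return inv_logit(eta)


def summarize_psi(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and 95% CI of psi per training site-season."""
    psi = predict_psi(draws)
    lo, hi = np.quantile(psi, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "site_id": draws.data.site_idx,
            "season": draws.data.season_idx,
            "psi_mean": psi.mean(axis=0),
            "psi_q2.5": lo,
            "psi_q97.5": hi,
        }
    )


def effect_curve(
    draws: PosteriorDraws, covariate: str, grid: np.ndarray
) -> pd.DataFrame:
    """Marginal occupancy-probability curve over one covariate.

    ``grid`` is on the standardized scale of the fitted design; all
    other covariates sit at their (zero) standardized means and the
    spatial effect at its prior mean of zero.
    """
    names = list(draws.data.occ_cov_names)
    if covariate not in names:
        raise ValueError(f"{covariate!r} is not an occupancy covariate: {names[1:]}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    j = names.index(covariate)
    x = np.zeros((grid.size, len(names)))
    x[:, 0] = 1.0
    x[:, j] = grid
    psi = inv_logit(draws.beta() @ x.T)
    lo, hi = np.quantile(psi, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"grid": grid, "psi_mean": psi.mean(axis=0), "psi_q2.5": lo, "psi_q97.5": hi}
    )
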