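"""Configuration, validation and end-to-end orchestration.

A run reads the five CSV inputs (or simulates them), fits the spatial
occupancy model and the activity GLMM, runs the goodness-of-fit and
convergence machinery, scores the detector, and writes a cross-model
comparison of the shared habitat covariates — the "multiple lines of
evidence" view.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .checking import (
    convergence_report,
    coverage_rate_95,
    posterior_predictive_check_glmm,
    posterior_predictive_check_occupancy,
    probability_of_direction,
)
from .detector import detector_metrics
from .glmm import GLMMData, GLMMPriorSpec, fit_activity_glmm, predict_activity
from .nngp import phi_prior_bounds
from .occupancy import (
    MCMCConfig,
    OccupancyModelData,
    PriorSpec,
    fit_occupancy,
    summarize_psi,
)
from .summaries import draws_to_long, summarize_posterior

log = logging.getLogger("pinebird")


@dataclass
class RunConfig:
    """One structured configuration; all randomness flows from ``seed``."""

    sites: str = "sites.csv"
    covariates: str = "covariates.csv"
    surveys: str = "surveys.csv"
    vocals: str = "vocals.csv"
    annotations: str = "annotations.csv"
    out_dir: str = "results"
    seed: int = 0
    # study defaults: occupancy 3 x 60000/30000/15, GLMM 3 x 60000/30000/20
    occ_chains: int = 3
    occ_iter: int = 60_000
    occ_burn: int = 30_000
    occ_thin: int = 15
    glmm_chains: int = 3
    glmm_iter: int = 60_000
    glmm_burn: int = 30_000
    glmm_thin: int = 20
    min_effective_range_km: float = 4.36
    max_effective_range_km: float = 84.31
    n_neighbors: int = 15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    def occupancy_mcmc(self) -> MCMCConfig:
        return MCMCConfig(self.occ_chains, self.occ_iter, self.occ_burn, self.occ_thin, self.seed)

    def glmm_mcmc(self) -> MCMCConfig:
        return MCMCConfig(
            self.glmm_chains, self.glmm_iter, self.glmm_burn, self.glmm_thin, self.seed
        )

    def occupancy_priors(self) -> PriorSpec:
        lo, hi = phi_prior_bounds(self.min_effective_range_km, self.max_effective_range_km)
        return PriorSpec(phi_lower=lo, phi_upper=hi)


@dataclass
class DatasetBundle:
    sites: pd.DataFrame
    covariates: pd.DataFrame
    surveys: pd.DataFrame
    vocals: pd.DataFrame
    annotations: pd.DataFrame
    warnings: list = field(default_factory=list)


def validate_inputs(config: RunConfig) -> DatasetBundle:
    """Load, schema-check and cross-check the five input tables.

    Violations are collected with row provenance and raised together;
    collinearity (|r| >= 0.7 between covariates entering a model) is a
    warning, not an error.
    """
    sites = pio.read_sites(config.sites)
    covariates = pio.read_covariates(config.covariates)
    surveys = pio.read_surveys(config.surveys)
    vocals = pio.read_vocals(config.vocals)
    annotations = pio.read_annotations(config.annotations)

    problems: list[str] = []
    known = set(sites["site_id"])
    for name, df in (("surveys", surveys), ("vocals", vocals), ("covariates", covariates)):
        bad = df.index[~df["site_id"].isin(known)]
        for i in bad[:20]:
            problems.append(f"{name}.csv row {i}: unknown site_id {df.at[i, 'site_id']}")

    bad = covariates.index[
        (covariates["prop_infected"] < 0) | (covariates["prop_infected"] > 1)
    ]
    for i in bad[:20]:
        problems.append(f"covariates.csv row {i}: prop_infected outside [0, 1]")
    for col in ("cone_density", "live_ba", "mean_dbh_cm", "total_ba"):
        bad = covariates.index[covariates[col] < 0]
        for i in bad[:20]:
            problems.append(f"covariates.csv row {i}: negative {col}")
    bad = vocals.index[vocals["n_vocalizations"] < 0]
    for i in bad[:20]:
        problems.append(f"vocals.csv row {i}: negative count")
    for col in ("tp", "fp", "fn"):
        bad = annotations.index[annotations[col] < 0]
        for i in bad[:20]:
            problems.append(f"annotations.csv row {i}: negative {col}")
    bad = surveys.index[~surveys["detected"].isin((0, 1))]
    for i in bad[:20]:
        problems.append(f"surveys.csv row {i}: detected must be 0/1")

    if problems:
        raise ValueError("input validation failed:\n" + "\n".join(problems))

    warns: list[str] = []
    occ_cols = ["year", "cone_density", "live_ba", "mean_dbh_cm", "prop_infected"]
    corr = covariates[occ_cols].corr().to_numpy()
    for a in range(len(occ_cols)):
        for b in range(a + 1, len(occ_cols)):
            if abs(corr[a, b]) >= 0.7:
                warns.append(
                    f"collinearity: |r({occ_cols[a]}, {occ_cols[b]})| = {abs(corr[a, b]):.2f} >= 0.7"
                )
    for w in warns:
        warnings.warn(w, stacklevel=2)
        log.warning(w)
    return DatasetBundle(sites, covariates, surveys, vocals, annotations, warns)


# shared habitat covariates, occupancy-parameter name vs GLMM-parameter name
_SHARED = {
    "cone_density": ("beta_cone", "glmm_cone"),
    "mean_dbh_cm": ("beta_dbh", "glmm_dbh"),
    "prop_infected": ("beta_infected", "glmm_infected"),
    "year": ("beta_year", "glmm_year"),
}


def comparison_report(occ_summary: pd.DataFrame, glmm_summary: pd.DataFrame) -> pd.DataFrame:
    """Align shared covariate effects across the two models.

    One row per covariate x model with posterior mean, 95% CI and the
    probability of a positive effect, plus a sign-agreement flag
    (posterior means on the same side of zero).  Covariates missing from
    either model (e.g. basal area, excluded from the GLMM) are omitted
    with a warning.
    """
    occ = occ_summary.set_index("parameter")
    glm = glmm_summary.set_index("parameter")
    rows = []
    for cov, (occ_name, glmm_name) in _SHARED.items():
        if occ_name not in occ.index or glmm_name not in glm.index:
            warnings.warn(f"covariate {cov} missing from one model; omitted", stacklevel=2)
            continue
        o, g = occ.loc[occ_name], glm.loc[glmm_name]
        agree = bool(np.sign(o["mean"]) == np.sign(g["mean"]))
        for model, s in (("occupancy", o), ("vocal_activity", g)):
            rows.append(
                {
                    "covariate": cov,
                    "model": model,
                    "mean": s["mean"],
                    "q2.5": s["q2.5"],
                    "q97.5": s["q97.5"],
                    "prob_positive": s["prob_direction"],
                    "sign_agreement": agree,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, bundle: DatasetBundle | None = None) -> dict:
    """End-to-end run; returns the result objects and writes all outputs."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("seed=%d", config.seed)
        if bundle is None:
            bundle = validate_inputs(config)
        log.info("validated inputs in %.1fs", time.time() - t_start)

        t0 = time.time()
        occ_data = OccupancyModelData.from_frames(
            bundle.sites, bundle.covariates, bundle.surveys
        )
        occ_fit = fit_occupancy(
            occ_data,
            priors=config.occupancy_priors(),
            config=config.occupancy_mcmc(),
            n_neighbors=config.n_neighbors,
        )
        log.info("occupancy fit in %.1fs", time.time() - t0)

        t0 = time.time()
        glmm_data = GLMMData.from_frames(bundle.vocals, bundle.covariates, bundle.sites)
        glmm_fit = fit_activity_glmm(
            glmm_data, priors=GLMMPriorSpec(), config=config.glmm_mcmc()
        )
        log.info("GLMM fit in %.1fs", time.time() - t0)

        t0 = time.time()
        checks = []
        for stat in ("freeman_tukey", "chi_squared"):
            for grouping in ("site", "replicate"):
                r = posterior_predictive_check_occupancy(
                    occ_fit, stat, grouping, seed=config.seed
                )
                checks.append(
                    {"model": "occupancy", "statistic": stat, "grouping": grouping,
                     "bayesian_p": r.bayesian_p}
                )
            for grouping in ("none", "site"):
                r = posterior_predictive_check_glmm(glmm_fit, stat, grouping, seed=config.seed)
                checks.append(
                    {"model": "vocal_activity", "statistic": stat, "grouping": grouping,
                     "bayesian_p": r.bayesian_p}
                )
        checks_df = pd.DataFrame(checks)

        rng = np.random.default_rng(config.seed)
        n_cov_draws = min(400, glmm_fit.fixed().shape[0])
        idx = rng.choice(glmm_fit.fixed().shape[0], size=n_cov_draws, replace=False)
        mu = glmm_fit.mu_draws(idx)
        kap = glmm_fit.kappa()[idx][:, None]
        y_rep = rng.negative_binomial(kap, kap / (kap + mu))
        coverage = coverage_rate_95(glmm_data.y, y_rep)

        occ_conv = convergence_report(occ_fit)
        glmm_conv = convergence_report(glmm_fit)
        conv_df = pd.concat(
            [occ_conv.table.assign(model="occupancy"),
             glmm_conv.table.assign(model="vocal_activity")],
            ignore_index=True,
        )
        log.info("model checking in %.1fs", time.time() - t0)

        occ_summary = summarize_posterior(occ_fit)
        glmm_summary = summarize_posterior(glmm_fit)
        comparison = comparison_report(occ_summary, glmm_summary)
        metrics = detector_metrics(bundle.annotations)
        psi_table = summarize_psi(occ_fit)

        # expected relative activity per site-season at the mean survey date
        cov = bundle.covariates.sort_values(["season", "site_id"]).reset_index(drop=True)
        gid = bundle.sites.set_index("site_id")["group_id"]
        act_rows = []
        for _, r in cov.iterrows():
            x = np.array(
                [[1.0, r["cone_density_std"], r["mean_dbh_cm_std"],
                  r["prop_infected_std"], r["year_std"], 0.0, 0.0]]
            )
            d = predict_activity(glmm_fit, x, int(gid.loc[r["site_id"]]))[:, 0]
            lo, hi = np.quantile(d, [0.025, 0.975])
            act_rows.append(
                {"site_id": int(r["site_id"]), "season": int(r["season"]),
                 "activity_mean": d.mean(), "activity_q2.5": lo, "activity_q97.5": hi}
            )
        activity_table = pd.DataFrame(act_rows)

        occ_summary.to_csv(out / "occupancy_summary.csv", index=False)
        glmm_summary.to_csv(out / "glmm_summary.csv", index=False)
        draws_to_long(occ_fit).to_csv(out / "occupancy_draws.csv", index=False)
        draws_to_long(glmm_fit).to_csv(out / "glmm_draws.csv", index=False)
        checks_df.to_csv(out / "checks.csv", index=False)
        conv_df.to_csv(out / "convergence.csv", index=False)
        comparison.to_csv(out / "comparison.csv", index=False)
        metrics.to_csv(out / "detector_metrics.csv", index=False)
        psi_table.to_csv(out / "psi_by_site_year.csv", index=False)
        activity_table.to_csv(out / "activity_by_site_year.csv", index=False)
        (out / "coverage_rate.txt").write_text(f"{coverage:.4f}\n")
        log.info("pipeline complete in %.1fs", time.time() - t_start)
    finally:
        log.removeHandler(handler)
        handler.close()

    return {
        "occupancy": occ_fit,
        "glmm": glmm_fit,
        "occupancy_summary": occ_summary,
        "glmm_summary": glmm_summary,
        "checks": checks_df,
        "convergence": conv_df,
        "coverage_rate": coverage,
        "comparison": comparison,
        "detector_metrics": metrics,
        "psi_by_site_year": psi_table,
        "activity_by_site_year": activity_table,
    }
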