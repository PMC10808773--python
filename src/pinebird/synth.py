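"""Synthetic paired point-count / acoustic survey data.

Generates data from exactly the hierarchy the two models assume: a
latent occupancy state per site-season with a spatially correlated
random effect on the logit scale, imperfect per-visit detection, and
overdispersed daily vocalization counts from a log-linear negative
binomial with group-varying date curves.  Marginals of the habitat
covariates are tuned to the right-skewed stand characteristics of the
whitebark pine inventory the design emulates (cone density mean >>
median, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SURVEY_DOY_WINDOW, StudyDesign, TrueParameters, rng_for

_MAX_PLACEMENT_ATTEMPTS = 5000

OCC_COVARIATES = ("year", "cone_density", "live_ba", "mean_dbh_cm", "prop_infected")
DET_COVARIATES = ("day_of_year", "wind", "total_ba", "year")
GLMM_COVARIATES = ("cone_density", "mean_dbh_cm", "prop_infected", "year", "day_of_year")


def inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _group_sizes(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    lo, hi = design.sites_per_group
    sizes = np.full(design.n_groups, lo, dtype=int)
    remaining = design.n_sites - sizes.sum()
    while remaining > 0:
        open_groups = np.flatnonzero(sizes < hi)
        g = rng.choice(open_groups)
        sizes[g] += 1
        remaining -= 1
    return sizes


def generate_landscape(design: StudyDesign) -> pd.DataFrame:
    """Place clustered sites on a planar-km landscape.

    Groups emulate drainages: 2-4 sites each, scattered within
    ``group_spread_km`` of a group centroid, with every pair of sites at
    least ``min_site_separation_km`` (default 0.3 km) apart.

    Returns a frame with columns site_id, x_km, y_km, group_id.
    """
    rng = rng_for(design.seed, 0)
    sizes = _group_sizes(design, rng)
    extent = design.landscape_extent_km
    centers = rng.uniform(design.group_spread_km, extent - design.group_spread_km,
                          size=(design.n_groups, 2))

    coords: list[np.ndarray] = []
    group_ids: list[int] = []
    for g in range(design.n_groups):
        for _ in range(sizes[g]):
            placed = False
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                offset = rng.uniform(-design.group_spread_km, design.group_spread_km, size=2)
                pt = centers[g] + offset
                if np.hypot(*offset) > design.group_spread_km:
                    continue
                if all(np.hypot(*(pt - q)) >= design.min_site_separation_km for q in coords):
                    coords.append(pt)
                    group_ids.append(g)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not honor the minimum site separation; "
                    "increase landscape_extent_km or group_spread_km"
                )
    xy = np.asarray(coords)
    return pd.DataFrame(
        {
            "site_id": np.arange(design.n_sites),
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "group_id": np.asarray(group_ids),
        }
    )


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def generate_covariates(sites: pd.DataFrame, design: StudyDesign, seed: int) -> pd.DataFrame:
    """Draw whitebark pine stand covariates per site and season.

    Cone density and blister-rust infection vary by site *and* season;
    live basal area, mean live DBH and total basal area are fixed site
    attributes.  Cone density is zero-inflated lognormal (right-skewed,
    mean well above median); infection proportion lives on [0.13, 1.0].
    Standardized copies (z-scored over this table) are stored alongside
    the raw values so simulation and inference share one scaling.
    """
    rng = rng_for(seed, 1)
    n = len(sites)
    t = design.n_seasons

    dbh = rng.lognormal(mean=np.log(4.0), sigma=1.15, size=n)
    live_ba = rng.lognormal(mean=np.log(4.0), sigma=1.7, size=n)
    total_ba = live_ba * (1.0 + rng.lognormal(mean=1.0, sigma=1.0, size=n))

    site_log_cone = rng.normal(np.log(25.0), 1.0, size=n)
    season_cone = rng.normal(0.0, 0.5, size=t)  # mast-year synchrony
    infected_base = rng.beta(2.2, 1.0, size=n)

    rows = []
    for s in range(t):
        log_cone = site_log_cone + season_cone[s] + rng.normal(0.0, 0.6, size=n)
        cone = np.round(np.exp(log_cone))
        cone[rng.random(n) < 0.15] = 0.0
        infected = np.clip(0.13 + 0.87 * (infected_base + rng.normal(0, 0.05, size=n)), 0.13, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "season": s,
                    "year": float(s),
                    "cone_density": cone,
                    "live_ba": live_ba,
                    "mean_dbh_cm": dbh,
                    "prop_infected": infected,
                    "total_ba": total_ba,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    for col in ("year", "cone_density", "live_ba", "mean_dbh_cm", "prop_infected", "total_ba"):
        df[col + "_std"] = _standardize(df[col].to_numpy(dtype=float))
    return df


def simulate_spatial_effects(
    sites: pd.DataFrame, sigma_sq: float, phi: float, seed: int
) -> np.ndarray:
    """Exact draw of the spatial random effect from the dense GP.

    Simulation uses the full covariance sigma^2 * exp(-phi d); the NNGP
    approximation is reserved for inference.
    """
    if sigma_sq <= 0 or phi <= 0:
        raise ValueError("sigma_sq and phi must be positive")
    rng = rng_for(seed, 2)
    xy = sites[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    cov = sigma_sq * np.exp(-phi * d)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "spatial covariance not positive definite; add coordinate jitter"
        ) from err
    return chol @ rng.standard_normal(len(xy))


@dataclass
class DetectionHistory:
    """Ragged binary visit histories plus the latent truth that produced them."""

    surveys: pd.DataFrame          # site_id, season, visit, day_of_year, wind, detected
    z: np.ndarray                  # (n_sites, n_seasons) latent occupancy
    psi: np.ndarray                # (n_sites, n_seasons) occupancy probabilities


def simulate_detections(
    covariates: pd.DataFrame,
    w: np.ndarray,
    truth: TrueParameters,
    design: StudyDesign,
    seed: int,
    sites: pd.DataFrame | None = None,
) -> DetectionHistory:
    """Draw latent occupancy and ragged detection histories.

    Occupancy: z ~ Bernoulli(inv_logit(X beta + w)); detection applies
    only where z = 1, with per-visit date (day-of-year 189-289), and
    wind covariates; visit counts are uniform on the design's range, so
    zero-visit site-seasons occur whenever the range allows them.
    """
    rng = rng_for(seed, 3)
    cov = covariates.sort_values(["season", "site_id"]).reset_index(drop=True)
    n, t = design.n_sites, design.n_seasons

    x_occ = np.column_stack(
        [
            np.ones(len(cov)),
            cov["year_std"],
            cov["cone_density_std"],
            cov["live_ba_std"],
            cov["mean_dbh_cm_std"],
            cov["prop_infected_std"],
        ]
    )
    site_idx = cov["site_id"].to_numpy(dtype=int)
    psi_flat = inv_logit(x_occ @ np.asarray(truth.beta) + np.asarray(w)[site_idx])
    z_flat = (rng.random(len(cov)) < psi_flat).astype(int)
    psi = psi_flat.reshape(t, n).T
    z = z_flat.reshape(t, n).T

    lo, hi = design.visits_per_site_season
    rows = []
    for r in range(len(cov)):
        k = int(rng.integers(lo, hi + 1))
        for visit in range(k):
            rows.append(
                (
                    int(cov.at[r, "site_id"]),
                    int(cov.at[r, "season"]),
                    visit,
                    int(rng.integers(SURVEY_DOY_WINDOW[0], SURVEY_DOY_WINDOW[1] + 1)),
                    int(rng.integers(0, 6)),  # Beaufort-like wind class
                    float(cov.at[r, "total_ba"]),
                    float(cov.at[r, "year"]),
                    z_flat[r],
                )
            )
    surveys = pd.DataFrame(
        rows,
        columns=["site_id", "season", "visit", "day_of_year", "wind", "total_ba", "year", "_z"],
    )
    if len(surveys):
        date_std = _standardize(surveys["day_of_year"].to_numpy(dtype=float))
        x_det = np.column_stack(
            [
                np.ones(len(surveys)),
                date_std,
                date_std**2,
                _standardize(surveys["wind"].to_numpy(dtype=float)),
                _standardize(surveys["total_ba"].to_numpy(dtype=float)),
                _standardize(surveys["year"].to_numpy(dtype=float)),
            ]
        )
        p = inv_logit(x_det @ np.asarray(truth.alpha))
        detected = ((rng.random(len(surveys)) < p) & (surveys["_z"].to_numpy() == 1)).astype(int)
    else:
        detected = np.zeros(0, dtype=int)
    surveys["detected"] = detected
    surveys = surveys.drop(columns=["_z", "total_ba", "year"])
    return DetectionHistory(surveys=surveys, z=z, psi=psi)


def simulate_vocal_counts(
    covariates: pd.DataFrame,
    truth: TrueParameters,
    design: StudyDesign,
    seed: int,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Daily negative-binomial vocalization counts per site-season.

    The log-mean combines the fixed effects (intercept, cone, DBH,
    infected, year, date, date^2 on standardized scales) with
    group-level random intercepts and random linear/quadratic date
    slopes drawn from zero-mean Gaussians with the design SDs.  Counts
    are NB with mean mu and size kappa (Var = mu + mu^2/kappa).
    """
    rng = rng_for(seed, 4)
    if sites is None:
        raise ValueError("sites table (with group_id) is required")
    group_of_site = sites.set_index("site_id")["group_id"]
    n_groups = int(group_of_site.max()) + 1
    sd0, sd1, sd2 = truth.glmm_group_sd
    u0 = rng.normal(0.0, sd0, size=n_groups) if sd0 > 0 else np.zeros(n_groups)
    u1 = rng.normal(0.0, sd1, size=n_groups) if sd1 > 0 else np.zeros(n_groups)
    u2 = rng.normal(0.0, sd2, size=n_groups) if sd2 > 0 else np.zeros(n_groups)

    lo, hi = design.recording_days_per_season
    window = np.arange(SURVEY_DOY_WINDOW[0], SURVEY_DOY_WINDOW[1] + 1)
    rows = []
    cov = covariates.sort_values(["season", "site_id"]).reset_index(drop=True)
    for r in range(len(cov)):
        n_days = int(rng.integers(lo, min(hi, len(window)) + 1))
        days = np.sort(rng.choice(window, size=n_days, replace=False))
        for d in days:
            rows.append((int(cov.at[r, "site_id"]), int(cov.at[r, "season"]), int(d), r))
    voc = pd.DataFrame(rows, columns=["site_id", "season", "day_of_year", "_covrow"])

    date_std = _standardize(voc["day_of_year"].to_numpy(dtype=float))
    covrow = voc["_covrow"].to_numpy()
    fixed = np.asarray(truth.glmm_fixed)
    x_fix = np.column_stack(
        [
            np.ones(len(voc)),
            cov["cone_density_std"].to_numpy()[covrow],
            cov["mean_dbh_cm_std"].to_numpy()[covrow],
            cov["prop_infected_std"].to_numpy()[covrow],
            cov["year_std"].to_numpy()[covrow],
            date_std,
            date_std**2,
        ]
    )
    g = group_of_site.loc[voc["site_id"]].to_numpy()
    eta = x_fix @ fixed + u0[g] + u1[g] * date_std + u2[g] * date_std**2
    mu = np.exp(eta)
    counts = rng.negative_binomial(truth.kappa, truth.kappa / (truth.kappa + mu))
    voc["n_vocalizations"] = counts
    voc = voc.drop(columns=["_covrow"])
    voc.attrs["group_effects"] = {"intercept": u0, "date": u1, "date2": u2}
    return voc


def simulate_annotation_tallies(
    n_segments: int,
    p_event: float,
    detector_recall: float,
    detector_precision: float,
    seed: int,
) -> pd.DataFrame:
    """True/false positive and false negative tallies per review segment.

    Models a human listening to short recording segments and scoring an
    automated detector: a segment holds vocalization events with
    probability ``p_event``; each event is found by the detector with
    probability ``detector_recall``; spurious detections arrive at a
    Poisson rate calibrated so the pooled expected precision equals
    ``detector_precision``.
    """
    for name, v in (
        ("p_event", p_event),
        ("detector_recall", detector_recall),
        ("detector_precision", detector_precision),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    if detector_precision == 0:
        raise ValueError("detector_precision must be positive")
    rng = rng_for(seed, 5)
    mean_events = 3.0
    events = rng.binomial(1, p_event, size=n_segments) * (1 + rng.poisson(mean_events - 1.0, size=n_segments))
    tp = rng.binomial(events, detector_recall)
    fn = events - tp
    fp_rate = p_event * mean_events * detector_recall * (1.0 - detector_precision) / detector_precision
    fp = rng.poisson(fp_rate, size=n_segments) if fp_rate > 0 else np.zeros(n_segments, dtype=int)
    return pd.DataFrame(
        {"segment_id": np.arange(n_segments), "tp": tp, "fp": fp, "fn": fn}
    )


@dataclass
class SyntheticDataset:
    """Complete paired synthetic survey bundle with generating truth."""

    design: StudyDesign
    truth: TrueParameters
    sites: pd.DataFrame
    covariates: pd.DataFrame
    surveys: pd.DataFrame
    vocals: pd.DataFrame
    annotations: pd.DataFrame
    w: np.ndarray
    z: np.ndarray
    psi: np.ndarray


def simulate_dataset(
    design: StudyDesign | None = None,
    truth: TrueParameters | None = None,
    seed: int | None = None,
    n_segments: int = 20,
    p_event: float = 0.7,
    detector_recall: float = 0.48,
    detector_precision: float = 1.0,
) -> SyntheticDataset:
    """Generate the full paired dataset (landscape through annotations)."""
    design = design or StudyDesign()
    truth = truth or TrueParameters()
    seed = design.seed if seed is None else seed
    if seed != design.seed:
        design = StudyDesign(**{**design.__dict__, "seed": seed})
    sites = generate_landscape(design)
    covariates = generate_covariates(sites, design, seed)
    w = simulate_spatial_effects(sites, truth.sigma_sq, truth.phi, seed)
    hist = simulate_detections(covariates, w, truth, design, seed, sites=sites)
    vocals = simulate_vocal_counts(covariates, truth, design, seed, sites=sites)
    annotations = simulate_annotation_tallies(
        n_segments, p_event, detector_recall, detector_precision, seed
    )
    return SyntheticDataset(
        design=design,
        truth=truth,
        sites=sites,
        covariates=covariates,
        surveys=hist.surveys,
        vocals=vocals,
        annotations=annotations,
        w=w,
        z=hist.z,
        psi=hist.psi,
    )
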