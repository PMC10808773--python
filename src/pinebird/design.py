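"""Study design description and generating parameters for the synthetic surveys.

The defaults mirror the field design the models were built for: 30
whitebark pine inventory sites clustered 2-4 per drainage (~10 drainages),
surveyed with 0-3 point counts per site in each of 3 harvest seasons, with
automated recording units logging 36-93 recording days per season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def point_count_survey_area_km2(radius_km: float = 0.1) -> float:
    """Area sampled by a fixed-radius point count (km^2).

    A 100 m radius gives pi * 0.1^2 ~= 0.0314 km^2.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    return math.pi * radius_km**2


def transect_area_m2(n_transects: int = 4, length_m: float = 50.0, width_m: float = 20.0) -> float:
    """Total stand-inventory area covered by the belt transects (m^2).

    Four cardinally oriented 50 x 20 m transects cover 4000 m^2; cone
    counts per site can be converted to per-ha densities with this area.
    """
    if n_transects < 1 or length_m <= 0 or width_m <= 0:
        raise ValueError("invalid transect geometry")
    return n_transects * length_m * width_m


@dataclass(frozen=True)
class StudyDesign:
    """Dimensions and sampling effort of a (synthetic) paired survey."""

    n_sites: int = 30
    n_seasons: int = 3
    visits_per_site_season: tuple[int, int] = (0, 3)
    n_groups: int = 10
    sites_per_group: tuple[int, int] = (2, 4)
    group_spread_km: float = 1.5
    landscape_extent_km: float = 60.0
    recording_days_per_season: tuple[int, int] = (36, 93)
    min_site_separation_km: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_seasons < 1 or self.n_groups < 1:
            raise ValueError("n_sites, n_seasons and n_groups must be >= 1")
        lo, hi = self.visits_per_site_season
        if not (0 <= lo <= hi <= 10):
            raise ValueError("visit range must satisfy 0 <= min <= max <= 10")
        if self.n_groups > self.n_sites:
            raise ValueError("cannot have more groups than sites")
        glo, ghi = self.sites_per_group
        if not (1 <= glo <= ghi):
            raise ValueError("invalid sites_per_group range")
        if not (glo * self.n_groups <= self.n_sites <= ghi * self.n_groups):
            raise ValueError("n_sites incompatible with sites_per_group range")
        for name in ("group_spread_km", "landscape_extent_km", "min_site_separation_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        rlo, rhi = self.recording_days_per_season
        if not (1 <= rlo <= rhi):
            raise ValueError("invalid recording-day range")


# Visit dates are drawn on the harvest-season window: day-of-year 189-289
# (July 8 to October 16, the earliest and latest surveys run).
SURVEY_DOY_WINDOW = (189, 289)


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of the occupancy hierarchy and the activity GLMM.

    ``beta`` are logit-scale occupancy coefficients for (intercept, year,
    cone density, live basal area, mean live DBH, proportion infected);
    ``alpha`` are logit-scale detection coefficients for (intercept, date,
    date^2, wind, total basal area, year).  ``glmm_fixed`` are log-scale
    coefficients for (intercept, cone, DBH, infected, year, date, date^2);
    all covariates enter standardized.  ``sigma_sq`` / ``phi`` parameterize
    the exponential spatial covariance sigma^2 * exp(-phi * d) (d in km);
    ``kappa`` is the negative-binomial size (overdispersion) parameter.

    Default magnitudes echo the posterior summaries reported for the
    Glacier National Park nutcracker surveys (strong positive cone and
    DBH effects, spatial variance ~1, effective range ~7.6 km, heavily
    overdispersed daily vocalization counts).
    """

    beta: tuple[float, ...] = (0.25, -0.4, 1.25, 0.75, 1.5, 0.25)
    alpha: tuple[float, ...] = (0.5, -0.5, -1.0, -0.3, 0.4, 0.0)
    sigma_sq: float = 1.0
    phi: float = 3.0 / 7.57
    glmm_fixed: tuple[float, ...] = (1.4, 0.45, 0.13, 0.12, -0.2, -0.3, -0.4)
    glmm_group_sd: tuple[float, float, float] = (0.7, 0.3, 0.2)
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if len(self.beta) != 6 or len(self.alpha) != 6:
            raise ValueError("beta and alpha must each have 6 entries")
        if len(self.glmm_fixed) != 7 or len(self.glmm_group_sd) != 3:
            raise ValueError("glmm_fixed needs 7 entries, glmm_group_sd needs 3")
        if self.sigma_sq <= 0 or self.phi <= 0 or self.kappa <= 0:
            raise ValueError("sigma_sq, phi and kappa must be positive")
        if any(s < 0 for s in self.glmm_group_sd):
            raise ValueError("group SDs must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, v in enumerate(self.beta):
            out[f"beta{i}"] = float(v)
        for i, v in enumerate(self.alpha):
            out[f"alpha{i}"] = float(v)
        out["sigma_sq"] = float(self.sigma_sq)
        out["phi"] = float(self.phi)
        names = ("intercept", "cone", "dbh", "infected", "year", "date", "date2")
        for n, v in zip(names, self.glmm_fixed):
            out[f"glmm_{n}"] = float(v)
        for n, v in zip(("intercept", "date", "date2"), self.glmm_group_sd):
            out[f"glmm_sd_{n}"] = float(v)
        out["kappa"] = float(self.kappa)
        return out


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Child generator derived from a master seed and integer stream keys."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=keys)))
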