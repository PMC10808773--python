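"""Plain-CSV persistence for the survey data schemas.

Schemas (all comma-separated, header row, no index column):

- sites.csv:        site_id, x_km, y_km, group_id
- covariates.csv:   site_id, season, year, cone_density, live_ba,
                    mean_dbh_cm, prop_infected, total_ba (+ *_std copies)
- surveys.csv:      site_id, season, visit, day_of_year, wind, detected
- vocals.csv:       site_id, season, day_of_year, n_vocalizations
- annotations.csv:  segment_id, tp, fp, fn
- truth.json:       flat name -> value map of generating parameters
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synth import SyntheticDataset

SITE_COLUMNS = ["site_id", "x_km", "y_km", "group_id"]
COVARIATE_COLUMNS = [
    "site_id", "season", "year", "cone_density", "live_ba",
    "mean_dbh_cm", "prop_infected", "total_ba",
]
SURVEY_COLUMNS = ["site_id", "season", "visit", "day_of_year", "wind", "detected"]
VOCAL_COLUMNS = ["site_id", "season", "day_of_year", "n_vocalizations"]
ANNOTATION_COLUMNS = ["segment_id", "tp", "fp", "fn"]


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns: {missing}")
    return df


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.csv",
        "covariates": out / "covariates.csv",
        "surveys": out / "surveys.csv",
        "vocals": out / "vocals.csv",
        "annotations": out / "annotations.csv",
        "truth": out / "truth.json",
    }
    dataset.sites.to_csv(paths["sites"], index=False)
    dataset.covariates.to_csv(paths["covariates"], index=False)
    dataset.surveys[SURVEY_COLUMNS].to_csv(paths["surveys"], index=False)
    dataset.vocals[VOCAL_COLUMNS].to_csv(paths["vocals"], index=False)
    dataset.annotations[ANNOTATION_COLUMNS].to_csv(paths["annotations"], index=False)
    truth = dataset.truth.as_dict()
    truth["seed"] = dataset.design.seed
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def read_sites(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), SITE_COLUMNS, "sites.csv")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = _check_columns(pd.read_csv(path), COVARIATE_COLUMNS, "covariates.csv")
    std_cols = [c for c in df.columns if c.endswith("_std")]
    if not std_cols:
        # raw-only table: standardize here with the documented z-scoring
        for col in ("year", "cone_density", "live_ba", "mean_dbh_cm",
                    "prop_infected", "total_ba"):
            v = df[col].to_numpy(dtype=float)
            sd = v.std()
            df[col + "_std"] = 0.0 if sd == 0 else (v - v.mean()) / sd
    return df


def read_surveys(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), SURVEY_COLUMNS, "surveys.csv")


def read_vocals(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), VOCAL_COLUMNS, "vocals.csv")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), ANNOTATION_COLUMNS, "annotations.csv")


def read_truth(path: str | Path) -> dict[str, float]:
    return json.loads(Path(path).read_text())
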