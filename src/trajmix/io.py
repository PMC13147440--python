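"""File formats and run metadata.

A single long-format CSV is the canonical interchange for cohorts
(one row per subject–wave), fitted models are stored as JSON, posterior
matrices as CSV, and publication-style tables as TSV.  Every artifact
written by the pipeline embeds the configuration hash, the seeds used and
the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

import trajmix
from trajmix.growth import FitResult, GrowthSpec, MixtureParams

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "write_fit",
    "read_fit",
    "write_posteriors",
    "read_posteriors",
    "run_metadata",
]

#: canonical cohort schema; oracle columns are prefixed ``true_`` and are
#: never consumed by modelling entry points
REQUIRED_COLUMNS = {
    "id": "integer subject identifier",
    "wave_time_years": "years since baseline (numeric)",
    "baseline_age": "age at enrolment in years",
    "female": "1 = female, 0 = male",
    "education": "elementary | high_school | university",
    "mmse": "global cognition, 0-30 (may be empty)",
    "daily_func": "combined (I)ADL score, 0-14 (may be empty)",
    "sh_participation": "social participation index (may be empty)",
    "sh_connections": "social connections index (may be empty)",
    "sh_support": "social support index (may be empty)",
}

_NUMERIC = (
    "wave_time_years",
    "baseline_age",
    "mmse",
    "daily_func",
    "sh_participation",
    "sh_connections",
    "sh_support",
)


class SchemaError(ValueError):
    """Raised with the full list of schema violations of a cohort file."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("cohort schema violations:\n  - " + "\n  - ".join(self.violations))


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Missing outcome cells stay missing; unknown extra columns are carried
    through untouched.  All schema violations are collected and reported
    together.
    """
    df = pd.read_csv(path)
    violations = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            violations.append(f"missing required column {col!r}")
    if violations:
        raise SchemaError(violations)
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for row in df.index[bad][:5]:
            violations.append(f"malformed value {df.loc[row, col]!r} in column {col!r}, row {row}")
        df[col] = coerced
    if violations:
        raise SchemaError(violations)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


def run_metadata(config: dict | None = None, seed: int | None = None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    return {
        "package": "trajmix",
        "version": trajmix.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest() if blob else None,
    }


def write_fit(fit: FitResult, path, config: dict | None = None, seed: int | None = None) -> None:
    payload = fit.to_dict()
    payload["metadata"] = run_metadata(config, seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fit(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    spec = GrowthSpec(**{**payload["spec"], "time_points": tuple(payload["spec"]["time_points"])})
    params = MixtureParams.from_dict(payload["params"])
    return FitResult(
        spec=spec,
        params=params,
        loglik=payload["loglik"],
        n_parameters=payload["n_parameters"],
        converged=payload["converged"],
        n_iterations=payload["n_iterations"],
        posteriors=np.empty((0, spec.n_classes)),
        n_subjects=payload["n_subjects"],
        degenerate=payload.get("degenerate", False),
    )


def write_posteriors(fit: FitResult, path) -> None:
    k = fit.posteriors.shape[1]
    df = pd.DataFrame(fit.posteriors, columns=[f"class_{j + 1}" for j in range(k)])
    df.insert(0, "id", fit.subject_ids)
    df.to_csv(path, index=False)


def read_posteriors(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or not any(c.startswith("class_") for c in df.columns):
        raise SchemaError(["posterior file needs an 'id' column and class_* columns"])
    return df


def schema_description() -> str:
    lines = ["column\tdescription"]
    for col, desc in REQUIRED_COLUMNS.items():
        lines.append(f"{col}\t{desc}")
    lines.append("true_*\toracle columns from the simulator (ignored by models)")
    return "\n".join(lines)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
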