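"""Construction of the five analysis outcomes from questionnaire-level data.

Social participation is a weighted sum of recoded activity frequencies
(each activity weighted by its mean-rated social component), social
connections and support are means of z-standardized items; all three are
rescaled to a T-like metric with mean 100 and SD 15 in the designated
baseline reference population, and follow-up scores always reuse the
baseline reference statistics.  Daily functioning combines basic (0–6)
and instrumental (0–8) activities-of-daily-living dependency counts into
a reverse-coded 0–14 score.  The module also applies the baseline
exclusion cascade with per-step accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceStats",
    "ActivityCatalog",
    "recode_frequency",
    "compute_participation_index",
    "compute_connection_index",
    "compute_support_index",
    "combine_daily_functioning",
    "apply_exclusions",
    "ExclusionAccounting",
]

T_MEAN = 100.0
T_SD = 15.0


@dataclass(frozen=True)
class ReferenceStats:
    """Mean and SD of a raw score in the baseline reference population."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("reference SD must be positive")

    @classmethod
    def from_series(cls, values) -> "ReferenceStats":
        v = pd.Series(values).dropna()
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)))

    def z(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


@dataclass(frozen=True)
class ActivityCatalog:
    """Leisure-activity weights: mean rater scores (0–3) per component.

    ``weights`` maps activity id -> (social, mental, physical) component
    weights; ``categories`` maps activity id -> its predominant category.
    """

    weights: dict
    categories: dict | None = None

    def __post_init__(self) -> None:
        for act, w in self.weights.items():
            if any(not (0.0 <= float(x) <= 3.0) for x in w):
                raise ValueError(f"component weights for {act!r} must lie in [0, 3]")

    def social_weight(self, activity: str) -> float:
        return float(self.weights[activity][0])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivityCatalog":
        """Build from a table with columns activity, category, w_social, w_mental, w_physical."""
        weights = {
            r["activity"]: (r["w_social"], r["w_mental"], r["w_physical"])
            for _, r in df.iterrows()
        }
        cats = dict(zip(df["activity"], df.get("category", pd.Series(dtype=str))))
        return cls(weights=weights, categories=cats or None)


def recode_frequency(raw_code):
    """Reverse the printed frequency coding so higher means more engagement.

    The questionnaire codes 0 = weekly, 1 = monthly, 2 = less frequently,
    3 = never; the engagement score is ``3 - code`` (weekly -> 3,
    never -> 0).  Accepts scalars or arrays; NaN passes through.
    """
    arr = np.asarray(raw_code, dtype=float)
    valid = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0, 3.0))
    if not np.all(valid):
        bad = arr[~valid].ravel()[0]
        raise ValueError(f"frequency code {bad!r} outside {{0, 1, 2, 3}}")
    out = 3.0 - arr
    if np.isscalar(raw_code) or np.ndim(raw_code) == 0:
        return float(out) if not np.isnan(out) else np.nan
    return out


def compute_participation_index(
    frequencies: pd.DataFrame,
    catalog: ActivityCatalog,
    ref: ReferenceStats,
) -> pd.Series:
    """Social participation index per subject.

    Each activity's recoded frequency is multiplied by its social
    component weight and summed; the total is z-standardized against the
    baseline reference (cognitively unimpaired participants) and mapped to
    ``100 + 15 z``.  Missing activity codes contribute zero, except that a
    subject missing every activity gets a missing index.
    """
    unknown = [c for c in frequencies.columns if c not in catalog.weights]
    if unknown:
        raise KeyError(f"activities missing from catalog: {unknown}")
    scores = recode_frequency(frequencies.to_numpy(dtype=float))
    w = np.array([catalog.social_weight(c) for c in frequencies.columns])
    weighted = scores * w[None, :]
    all_missing = np.isnan(scores).all(axis=1)
    raw = np.nansum(weighted, axis=1)
    raw[all_missing] = np.nan
    return pd.Series(T_MEAN + T_SD * ref.z(raw), index=frequencies.index, name="sh_participation")


def _composite_index(
    items: pd.DataFrame,
    item_refs: dict,
    average_ref: ReferenceStats,
    name: str,
) -> pd.Series:
    z = pd.DataFrame(index=items.index)
    for col in items.columns:
        z[col] = item_refs[col].z(items[col].to_numpy(dtype=float))
    avg = z.mean(axis=1, skipna=True)  # over non-missing items; all-missing -> NaN
    return pd.Series(T_MEAN + T_SD * average_ref.z(avg.to_numpy()), index=items.index, name=name)


def compute_connection_index(items, item_refs, average_ref) -> pd.Series:
    """Social connections index: mean of item z-scores, T-rescaled.

    Items (relationship status, living arrangement, number of children,
    contact frequency, network size) are z-standardized against baseline
    item references, averaged over the subject's non-missing items, and
    the average is rescaled against the baseline distribution of that
    average so that 100 marks the study-population mean.
    """
    return _composite_index(items, item_refs, average_ref, "sh_connections")


def compute_support_index(items, item_refs, average_ref) -> pd.Series:
    """Social support index (satisfaction, material/psychological support,
    affinity); same construction as the connections index."""
    return _composite_index(items, item_refs, average_ref, "sh_support")


def combine_daily_functioning(adl_dependencies, iadl_dependencies):
    """Reverse-coded combined daily-functioning score.

    ``14 - (ADL dependencies + IADL dependencies)`` with ADL counts in
    0–6 and IADL counts in 0–8; higher means better functioning.
    """
    adl = np.asarray(adl_dependencies, dtype=float)
    iadl = np.asarray(iadl_dependencies, dtype=float)
    if np.any((adl < 0) | (adl > 6) | (np.mod(adl, 1) != 0) & ~np.isnan(adl)):
        raise ValueError("ADL dependency counts must be integers in 0..6")
    if np.any((iadl < 0) | (iadl > 8) | (np.mod(iadl, 1) != 0) & ~np.isnan(iadl)):
        raise ValueError("IADL dependency counts must be integers in 0..8")
    out = 14.0 - (adl + iadl)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ExclusionAccounting:
    n_input: int
    steps: list  # (label, n_excluded, n_remaining)
    n_final: int


_EXCLUSION_ORDER = (
    ("neuropsych", "neuropsychiatric disorder"),
    ("nursing_home", "living in nursing home"),
    ("all_sh_missing", "missing all social-health variables"),
)


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionAccounting]:
    """Apply the baseline exclusion cascade with per-step accounting.

    Keeps subjects who completed the cognitive screen and are free of
    baseline dementia, then sequentially excludes neuropsychiatric
    disorders, nursing-home residence, and subjects missing all
    social-health variables; a subject carrying several flags is counted
    at the first applicable step.  Flag columns are ``excl_<flag>`` plus
    ``mmse_completed`` and optionally ``baseline_dementia``.
    """
    required = ["mmse_completed"] + [f"excl_{flag}" for flag, _ in _EXCLUSION_ORDER]
    missing = [c for c in required if c not in roster.columns]
    if missing:
        raise KeyError(f"roster lacks required columns: {missing}")
    steps = []
    current = roster
    n0 = len(current)
    mask = current["mmse_completed"].astype(bool)
    if "baseline_dementia" in current.columns:
        mask &= ~current["baseline_dementia"].astype(bool)
    current = current[mask]
    if (n0 - len(current)) > 0:
        steps.append(("screen incomplete or baseline dementia", n0 - len(current), len(current)))
    n_input = len(current)
    for flag, label in _EXCLUSION_ORDER:
        before = len(current)
        current = current[~current[f"excl_{flag}"].astype(bool)]
        steps.append((label, before - len(current), len(current)))
    return current.reset_index(drop=True), ExclusionAccounting(
        n_input=n_input, steps=steps, n_final=len(current)
    )
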