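"""Seeded generator of synthetic ageing cohorts with known class structure.

The generator emulates the design of an age-stratified Swedish urban ageing
cohort: fixed enrolment ages, cohort-specific visit schedules (every six
years below age 78, every three years from 78 on), class-structured
quadratic outcome trajectories whose growth parameters interact with
baseline age, covariate-dependent latent class membership, cross-domain
class coupling with target odds ratios, and monotone (missing-at-random)
dropout.  Every simulated table carries oracle ``true_*`` columns so that
downstream estimators can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ClassTrajectory",
    "MembershipModel",
    "DomainModel",
    "Coupling",
    "DropoutModel",
    "ScenarioConfig",
    "OUTCOME_COLUMNS",
    "EDUCATION_LEVELS",
    "couple_classes_by_or",
    "draw_baseline_roster",
    "assign_classes",
    "simulate_outcome",
    "simulate_cohort",
]

#: long-table column name for each outcome domain
OUTCOME_COLUMNS: dict[str, str] = {
    "cognition": "mmse",
    "daily_functioning": "daily_func",
    "participation": "sh_participation",
    "connections": "sh_connections",
    "support": "sh_support",
}

EDUCATION_LEVELS = ("elementary", "high_school", "university")

#: age at and above which the three-year visit cadence applies
OLD_COHORT_AGE = 78.0
YOUNG_WAVES = (0.0, 6.0, 12.0)
OLD_WAVES = (0.0, 3.0, 6.0, 9.0, 12.0)

#: baseline age is centred here throughout the package
AGE_CENTER = 60.0


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ClassTrajectory:
    """Quadratic mean trajectory of one latent class.

    The outcome of a subject with centred baseline age ``a`` observed at
    wave time ``t`` (years since baseline) is

    ``y(t) = (beta0 + gamma0*a) + (beta1 + gamma1*a)*t + (beta2 + gamma2*a)*t^2
    + b0 + b1*t + eps(t)``

    with random effects ``(b0, b1) ~ N(0, re_cov)`` drawn once per subject
    and independent residuals ``eps(t) ~ N(0, resid_var)``.
    """

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    gamma0: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    #: random-effect covariance; shape (0,0), (1,1) or (2,2) over (intercept, slope)
    re_cov: tuple = ()
    #: residual variance, one shared value or one per planned wave
    resid_var: float | tuple = 1.0
    #: optional (lo, hi) clamp applied on the observed scale
    bounds: tuple | None = None

    def __post_init__(self) -> None:
        cov = np.atleast_2d(np.asarray(self.re_cov, dtype=float)) if len(self.re_cov) else np.zeros((0, 0))
        if cov.size:
            if not np.allclose(cov, cov.T):
                raise ConfigurationError("re_cov must be symmetric")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
                raise ConfigurationError("re_cov must be positive semi-definite")
        if np.any(np.asarray(self.resid_var, dtype=float) <= 0):
            raise ConfigurationError("resid_var must be positive")

    @property
    def re_cov_matrix(self) -> np.ndarray:
        cov = np.asarray(self.re_cov, dtype=float)
        return np.atleast_2d(cov) if cov.size else np.zeros((0, 0))

    def mean(self, times: np.ndarray, age_centered: float | np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        a = np.asarray(age_centered, dtype=float)
        if a.ndim == 0:
            return (
                (self.beta0 + self.gamma0 * a)
                + (self.beta1 + self.gamma1 * a) * t
                + (self.beta2 + self.gamma2 * a) * t**2
            )
        # vectorized over subjects: result (n, len(t))
        a = a[:, None]
        return (
            (self.beta0 + self.gamma0 * a)
            + (self.beta1 + self.gamma1 * a) * t[None, :]
            + (self.beta2 + self.gamma2 * a) * t[None, :] ** 2
        )


@dataclass(frozen=True)
class MembershipModel:
    """Multinomial logit for latent class membership (class 1 = reference).

    Linear predictors use the covariate vector
    ``(centred baseline age, female, high_school, university)``.
    """

    intercepts: tuple  # (K-1,)
    coefs: tuple = ()  # (K-1, 4) rows: (age, female, edu_hs, edu_uni)

    @property
    def n_classes(self) -> int:
        return len(self.intercepts) + 1

    def probabilities(self, covariates: np.ndarray) -> np.ndarray:
        """Class probabilities; ``covariates`` is (n, 4)."""
        x = np.asarray(covariates, dtype=float)
        alpha = np.asarray(self.intercepts, dtype=float)
        if len(self.coefs):
            gamma = np.asarray(self.coefs, dtype=float).reshape(len(alpha), x.shape[1])
            eta = alpha[None, :] + x @ gamma.T
        else:
            eta = np.broadcast_to(alpha[None, :], (x.shape[0], len(alpha))).copy()
        eta = np.concatenate([np.zeros((x.shape[0], 1)), eta], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class DomainModel:
    """Latent class structure of one outcome domain."""

    membership: MembershipModel
    classes: tuple  # tuple[ClassTrajectory, ...] ordered class 1..K

    def __post_init__(self) -> None:
        if self.membership.n_classes != len(self.classes):
            raise ConfigurationError(
                "membership model and trajectory list disagree on the number of classes"
            )


@dataclass(frozen=True)
class Coupling:
    """Target odds ratio between class indicators of two domains.

    ``domain_a``/``class_a`` may be tuples describing a composite pattern,
    e.g. ``(("cognition", "daily_functioning"), (2, 1))`` for the
    discordant low-cognition / preserved-functioning pattern.  The
    coupling is applied conditionally on covariates via the Plackett
    construction in :func:`couple_classes_by_or`.
    """

    domain_a: str | tuple
    class_a: int | tuple
    domain_b: str
    class_b: int
    psi: float

    def __post_init__(self) -> None:
        if self.psi <= 0:
            raise ConfigurationError("coupling odds ratio must be strictly positive")


@dataclass(frozen=True)
class DropoutModel:
    """Per-visit logistic dropout hazard (monotone, missing at random).

    At each planned follow-up visit the probability of dropping out before
    that visit is ``expit(intercept + age_coef*a + outcome_coef*z)`` where
    ``a`` is centred baseline age and ``z`` the standardized value of
    ``outcome_domain`` at the previous observed visit.
    """

    intercept: float
    age_coef: float = 0.0
    outcome_coef: float = 0.0
    outcome_domain: str | None = None
    outcome_center: float = 0.0
    outcome_scale: float = 1.0


def default_visit_schedule(baseline_age: float) -> tuple:
    """Planned wave times in years for a given enrolment age."""
    return OLD_WAVES if baseline_age >= OLD_COHORT_AGE else YOUNG_WAVES


@dataclass
class ScenarioConfig:
    """Full description of one synthetic-cohort scenario."""

    n_subjects: int
    baseline_age_strata: tuple  # ((age, weight), ...)
    outcome_models: Mapping[str, DomainModel]
    sex_prevalence: float = 0.63
    education_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"elementary": 0.35, "high_school": 0.50, "university": 0.15}
    )
    cross_domain_or: tuple = ()
    dropout_model: DropoutModel | None = None
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {"neuropsych": 0.0, "nursing_home": 0.0, "all_sh_missing": 0.0}
    )
    visit_schedule_rule: Callable[[float], tuple] = default_visit_schedule
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.baseline_age_strata:
            raise ConfigurationError("baseline_age_strata must be non-empty")
        w = np.array([s[1] for s in self.baseline_age_strata], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("stratum weights must be non-negative and sum to 1")
        e = np.array([self.education_distribution[k] for k in EDUCATION_LEVELS])
        if np.any(e < 0) or not np.isclose(e.sum(), 1.0):
            raise ConfigurationError("education probabilities must sum to 1")
        if not 0.0 <= self.sex_prevalence <= 1.0:
            raise ConfigurationError("sex_prevalence must be a probability")
        for c in self.cross_domain_or:
            if c.domain_b not in self.outcome_models:
                raise ConfigurationError(f"unknown coupled domain {c.domain_b!r}")
            for d in (c.domain_a if isinstance(c.domain_a, tuple) else (c.domain_a,)):
                if d not in self.outcome_models:
                    raise ConfigurationError(f"unknown coupled domain {d!r}")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# coupling


def couple_classes_by_or(p_margin, q_margin, psi):
    """Joint 2x2 cell probabilities with given margins and odds ratio.

    Returns an array ``cells`` of shape (..., 2, 2) with
    ``cells[..., a, b] = P(A=a, B=b)`` for indicators A, B such that
    ``P(A=1) = p_margin``, ``P(B=1) = q_margin`` and the cross-product
    ratio equals ``psi`` (the Plackett construction: the admissible root
    of the quadratic in the (1,1) cell).  ``psi=1`` yields independence.
    """
    p = np.asarray(p_margin, dtype=float)
    q = np.asarray(q_margin, dtype=float)
    if np.any((p <= 0) | (p >= 1)) or np.any((q <= 0) | (q >= 1)):
        raise ValueError("margins must lie strictly inside (0, 1)")
    if psi <= 0:
        raise ValueError("psi must be strictly positive")
    a = psi - 1.0
    if abs(a) < 1e-12:
        p11 = p * q
    else:
        b = 1.0 + a * (p + q)
        disc = b * b - 4.0 * a * psi * p * q
        p11 = (b - np.sqrt(disc)) / (2.0 * a)
    p11 = np.clip(p11, np.maximum(0.0, p + q - 1.0), np.minimum(p, q))
    cells = np.empty(np.shape(p11) + (2, 2))
    cells[..., 1, 1] = p11
    cells[..., 1, 0] = p - p11
    cells[..., 0, 1] = q - p11
    cells[..., 0, 0] = 1.0 - p - q + p11
    return cells


# ---------------------------------------------------------------------------
# roster


def draw_baseline_roster(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the baseline roster: ages, sex, education and exclusion flags.

    Returns one row per subject with the planned visit schedule implied by
    the enrolment age.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    ages = np.array([s[0] for s in config.baseline_age_strata], dtype=float)
    weights = np.array([s[1] for s in config.baseline_age_strata], dtype=float)
    baseline_age = rng.choice(ages, size=n, p=weights)
    female = rng.random(n) < config.sex_prevalence
    edu_p = np.array([config.education_distribution[k] for k in EDUCATION_LEVELS])
    education = rng.choice(np.arange(3), size=n, p=edu_p)
    roster = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "baseline_age": baseline_age,
            "female": female.astype(int),
            "education": pd.Categorical.from_codes(education, categories=list(EDUCATION_LEVELS)),
        }
    )
    for flag in ("neuropsych", "nursing_home", "all_sh_missing"):
        rate = float(config.exclusion_rates.get(flag, 0.0))
        roster[f"excl_{flag}"] = (rng.random(n) < rate).astype(int)
    roster["planned_waves"] = [config.visit_schedule_rule(a) for a in baseline_age]
    return roster


def _covariate_matrix(roster: pd.DataFrame) -> np.ndarray:
    edu = roster["education"].astype(str).to_numpy()
    return np.column_stack(
        [
            roster["baseline_age"].to_numpy(dtype=float) - AGE_CENTER,
            roster["female"].to_numpy(dtype=float),
            (edu == "high_school").astype(float),
            (edu == "university").astype(float),
        ]
    )


def assign_classes(
    roster: pd.DataFrame, config: ScenarioConfig, seed: int | None = None
) -> pd.DataFrame:
    """Assign true latent classes per domain, honouring cross-domain couplings.

    Domains are drawn in configuration order; a domain appearing as the
    ``domain_b`` side of a coupling is drawn conditionally on the realized
    ``domain_a`` indicator so that the covariate-conditional odds ratio
    between the two class indicators equals ``psi``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    x = _covariate_matrix(roster)
    n = len(roster)
    roster = roster.copy()
    couplings_by_b = {}
    for c in config.cross_domain_or:
        if c.domain_b in couplings_by_b:
            raise ConfigurationError(f"domain {c.domain_b!r} coupled more than once as target")
        couplings_by_b[c.domain_b] = c
    # per-(domain, class) marginal indicator probabilities, for composites
    indicator_prob: dict[tuple, np.ndarray] = {}
    pair_cells: dict[tuple, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}

    for domain, model in config.outcome_models.items():
        probs = model.membership.probabilities(x)  # (n, K)
        for k in range(model.membership.n_classes):
            indicator_prob[(domain, k + 1)] = probs[:, k]
        c = couplings_by_b.get(domain)
        if c is None:
            u = rng.random(n)
            labels[domain] = 1 + (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
            continue
        # conditional draw against the realized domain_a indicator
        if isinstance(c.domain_a, tuple):
            ind_a, p_a = _composite_indicator(c, labels, indicator_prob, pair_cells)
        else:
            if c.domain_a not in labels:
                raise ConfigurationError(
                    f"coupling source {c.domain_a!r} must be drawn before {domain!r}"
                )
            ind_a = (labels[c.domain_a] == c.class_a).astype(int)
            p_a = indicator_prob[(c.domain_a, c.class_a)]
        p_b = probs[:, c.class_b - 1]
        cells = couple_classes_by_or(p_a, p_b, c.psi)
        pair_cells[(c.domain_a, c.class_a, domain, c.class_b)] = cells
        with np.errstate(invalid="ignore"):
            p_cond = np.where(
                ind_a == 1,
                cells[:, 1, 1] / p_a,
                cells[:, 0, 1] / (1.0 - p_a),
            )
        in_target = rng.random(n) < p_cond
        lab = np.empty(n, dtype=int)
        lab[in_target] = c.class_b
        others = [k for k in range(1, model.membership.n_classes + 1) if k != c.class_b]
        rest = ~in_target
        if len(others) == 1:
            lab[rest] = others[0]
        else:
            po = probs[np.ix_(rest, [k - 1 for k in others])]
            po = po / po.sum(axis=1, keepdims=True)
            u = rng.random(rest.sum())
            lab[rest] = np.asarray(others)[(u[:, None] > po.cumsum(axis=1)).sum(axis=1)]
        labels[domain] = lab

    for domain, lab in labels.items():
        roster[f"true_class_{domain}"] = lab
    return roster


def _composite_indicator(c: Coupling, labels, indicator_prob, pair_cells):
    """Realized indicator and per-subject probability of a composite pattern."""
    (da, db), (ka, kb) = c.domain_a, c.class_a
    for d in (da, db):
        if d not in labels:
            raise ConfigurationError(f"composite source {d!r} must be drawn before {c.domain_b!r}")
    ind = ((labels[da] == ka) & (labels[db] == kb)).astype(int)
    # exact joint probability if the two source domains were themselves coupled
    for (a_dom, a_cls, b_dom, b_cls), cells in pair_cells.items():
        if (a_dom, b_dom) == (da, db):
            ia = 1 if a_cls == ka else 0
            ib = 1 if b_cls == kb else 0
            return ind, cells[:, ia, ib]
    prob = indicator_prob[(da, ka)] * indicator_prob[(db, kb)]
    return ind, prob


# ---------------------------------------------------------------------------
# outcomes


def simulate_outcome(
    ages_centered: np.ndarray,
    times: Sequence[float],
    trajectory: ClassTrajectory,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate outcome values for subjects sharing one visit schedule.

    Returns an array (n_subjects, n_waves).  Random effects are drawn once
    per subject, residuals independently per wave; values are clamped to
    the trajectory bounds if set.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("waves must be non-empty")
    a = np.atleast_1d(np.asarray(ages_centered, dtype=float))
    y = trajectory.mean(t, a)
    cov = trajectory.re_cov_matrix
    q = cov.shape[0]
    if q:
        z = np.vstack([np.ones_like(t), t])[:q]  # (q, T)
        b = rng.multivariate_normal(np.zeros(q), cov, size=a.shape[0], method="cholesky")
        y = y + b @ z
    rv = np.asarray(trajectory.resid_var, dtype=float)
    sd = np.sqrt(np.broadcast_to(rv, t.shape) if rv.ndim else np.full(t.shape, rv))
    y = y + rng.standard_normal(y.shape) * sd
    if trajectory.bounds is not None:
        y = np.clip(y, trajectory.bounds[0], trajectory.bounds[1])
    return y


def _apply_dropout(
    roster: pd.DataFrame,
    wide: dict[str, dict[int, np.ndarray]],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Observed-wave mask per subject (list of boolean arrays over planned waves)."""
    model = config.dropout_model
    masks = []
    if model is None:
        for waves in roster["planned_waves"]:
            masks.append(np.ones(len(waves), dtype=bool))
        return masks
    dom = model.outcome_domain or next(iter(config.outcome_models))
    ages = roster["baseline_age"].to_numpy(dtype=float) - AGE_CENTER
    for i, (idx, row) in enumerate(roster.iterrows()):
        waves = row["planned_waves"]
        m = np.ones(len(waves), dtype=bool)
        yvals = wide[dom][row["id"]]
        for j in range(1, len(waves)):
            z = (yvals[j - 1] - model.outcome_center) / model.outcome_scale
            p = expit(model.intercept + model.age_coef * ages[i] + model.outcome_coef * z)
            if rng.random() < p:
                m[j:] = False
                break
        masks.append(m)
    return masks


def simulate_cohort(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a long-format cohort table for the configured scenario.

    Driver: baseline roster -> latent classes -> class-conditional outcome
    trajectories -> monotone dropout -> long table.  The ``true_*`` columns
    are ground-truth oracles for testing only and are ignored by every
    modelling entry point in this package.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_roster, s_classes, s_outcome, s_dropout = ss.spawn(4)
    roster = draw_baseline_roster(config, seed=s_roster)
    roster = assign_classes(roster, config, seed=s_classes)
    rng_out = np.random.default_rng(s_outcome)
    ages_c = roster["baseline_age"].to_numpy(dtype=float) - AGE_CENTER

    # simulate per (schedule, domain, class) block for vectorization
    schedule_key = roster["planned_waves"].map(tuple)
    wide: dict[str, dict[int, np.ndarray]] = {d: {} for d in config.outcome_models}
    for sched in sorted(schedule_key.unique()):
        sel = (schedule_key == sched).to_numpy()
        for domain, model in config.outcome_models.items():
            lab = roster[f"true_class_{domain}"].to_numpy()
            for k, traj in enumerate(model.classes, start=1):
                pick = sel & (lab == k)
                if not pick.any():
                    continue
                vals = simulate_outcome(ages_c[pick], sched, traj, rng_out)
                for row_id, v in zip(roster.loc[pick, "id"], vals):
                    wide[domain][row_id] = v

    rng_drop = np.random.default_rng(s_dropout)
    masks = _apply_dropout(roster, wide, config, rng_drop)

    records = []
    for i, (_, row) in enumerate(roster.iterrows()):
        waves = np.asarray(row["planned_waves"], dtype=float)
        for j, t in enumerate(waves):
            if not masks[i][j]:
                break
            rec = {
                "id": row["id"],
                "wave_time_years": t,
                "baseline_age": row["baseline_age"],
                "female": row["female"],
                "education": str(row["education"]),
            }
            for domain, col in OUTCOME_COLUMNS.items():
                rec[col] = wide[domain][row["id"]][j] if domain in wide else np.nan
            records.append(rec)
    table = pd.DataFrame.from_records(records)

    keep = ["id"] + [c for c in roster.columns if c.startswith(("true_class_", "excl_"))]
    table = table.merge(roster[keep], on="id")
    return table.sort_values(["id", "wave_time_years"], kind="stable").reset_index(drop=True)
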