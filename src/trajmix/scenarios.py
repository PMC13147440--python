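"""Packaged synthetic-cohort scenarios.

Each scenario fixes the study conditions for one analysis domain of an
age-stratified urban ageing cohort: enrolment ages 60–90 with a six-year
visit cadence below 78 and a three-year cadence from 78 on, roughly 63%
women, and an education mix of 35% elementary / 50% high school / 15%
university.  Class trajectory shapes, class proportions, baseline-age
effects on the growth parameters, covariate effects on class membership
and cross-domain couplings are calibrated to published estimates from a
2,848-person cohort analysis of these five outcomes:

* ``cognition`` — MMSE, two classes: preserved (91%) and fast decline
  (9%); within-class baseline-age effects −0.045 on the intercept,
  −0.007 on the linear and −0.001 on the quadratic slope.
* ``daily_functioning`` — combined (I)ADL score, two classes: stable
  (95%) and declining (5%, intercept 8.9 and linear slope −0.21 for a
  60-year-old); age effects −0.019 / −0.01 / −0.001.
* ``participation`` — social participation index, two classes (30% / 70%),
  baseline-age effect −0.74 on the intercept.
* ``connections`` — social connections index, two classes (71% / 29%),
  baseline-age effect −0.25 on the intercept; female odds ratio 1.36 for
  the initially-lower class.
* ``support`` — social support index, three classes: stable (95%),
  declining (2%) and increasing (3%).
* ``joint`` — cognition, daily functioning and support together, with the
  declining-cognition / declining-functioning coupling set to an odds
  ratio of 7.31 and the increasing-support / discordant
  (low-cognition, preserved-functioning) coupling set to 4.2.
* ``attenuation`` — a deliberately noisier two-class variant of the
  connections design (classification entropy around 0.7) for exercising
  the bias correction of covariate–class regressions.

Membership-logit intercepts are calibrated at build time so that the
implied marginal class shares equal the target proportions exactly under
the configured covariate distribution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq, root

from trajmix.cohort import (
    AGE_CENTER,
    EDUCATION_LEVELS,
    ClassTrajectory,
    Coupling,
    DomainModel,
    DropoutModel,
    MembershipModel,
    ScenarioConfig,
)

__all__ = ["available_scenarios", "make_scenario", "DEFAULT_AGE_STRATA"]

#: enrolment ages and sampling weights (mean baseline age ~72, 26% aged 81+)
DEFAULT_AGE_STRATA = (
    (60.0, 0.22),
    (66.0, 0.22),
    (72.0, 0.16),
    (78.0, 0.14),
    (81.0, 0.10),
    (84.0, 0.08),
    (87.0, 0.05),
    (90.0, 0.03),
)

SEX_PREVALENCE = 0.63
EDUCATION_DISTRIBUTION = {"elementary": 0.35, "high_school": 0.50, "university": 0.15}


def _covariate_cells(age_strata, sex_prev, edu_dist):
    """Exact joint distribution over the discrete covariate support."""
    cells, weights = [], []
    for age, wa in age_strata:
        for female, wf in ((1.0, sex_prev), (0.0, 1 - sex_prev)):
            for e_i, level in enumerate(EDUCATION_LEVELS):
                we = edu_dist[level]
                x = (age - AGE_CENTER, female, 1.0 if e_i == 1 else 0.0, 1.0 if e_i == 2 else 0.0)
                cells.append(x)
                weights.append(wa * wf * we)
    return np.asarray(cells), np.asarray(weights)


def calibrate_membership(
    target_shares,
    coefs,
    age_strata=DEFAULT_AGE_STRATA,
    sex_prev=SEX_PREVALENCE,
    edu_dist=EDUCATION_DISTRIBUTION,
) -> MembershipModel:
    """Solve the membership-logit intercepts for exact marginal class shares.

    ``target_shares`` are the desired marginal probabilities of classes
    2..K; ``coefs`` the (K-1, 4) covariate effects on the class logits
    (log odds ratios for centred age, female, high-school and university
    vs elementary).  The expectation over the finite covariate support is
    exact, so the returned intercepts reproduce the target shares exactly
    in the infinite-sample limit.
    """
    x, w = _covariate_cells(age_strata, sex_prev, edu_dist)
    target = np.asarray(target_shares, dtype=float)
    cf = np.asarray(coefs, dtype=float).reshape(len(target), 4)
    eta_x = x @ cf.T  # (cells, K-1)

    def shares(alpha):
        eta = np.concatenate([np.zeros((x.shape[0], 1)), alpha[None, :] + eta_x], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return w @ p[:, 1:]

    if len(target) == 1:
        lo, hi = -20.0, 20.0
        alpha = np.array([brentq(lambda a: shares(np.array([a]))[0] - target[0], lo, hi)])
    else:
        sol = root(lambda a: shares(a) - target, x0=np.log(target / (1 - target.sum())), tol=1e-12)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"membership calibration failed: {sol.message}")
        alpha = sol.x
    return MembershipModel(intercepts=tuple(alpha), coefs=tuple(map(tuple, cf)))


def _log(x):
    return math.log(x)


# ---------------------------------------------------------------------------
# domain builders (trajectory shapes; printed values noted per domain above)


def _cognition_domain(covariate_effects=True) -> DomainModel:
    gamma = dict(gamma0=-0.045, gamma1=-0.007, gamma2=-0.001)
    re_cov = ((0.5, -0.004), (-0.004, 0.003))
    classes = (
        ClassTrajectory(beta0=27.8, beta1=-0.05, beta2=-0.004, re_cov=re_cov,
                        resid_var=0.5, bounds=(0.0, 30.0), **gamma),
        ClassTrajectory(beta0=25.5, beta1=-0.45, beta2=-0.055, re_cov=re_cov,
                        resid_var=0.5, bounds=(0.0, 30.0), **gamma),
    )
    coefs = ((_log(1.11), _log(1.33), _log(0.54), _log(0.30)),) if covariate_effects else ((0, 0, 0, 0),)
    membership = calibrate_membership((0.09,), coefs)
    return DomainModel(membership=membership, classes=classes)


def _daily_functioning_domain(covariate_effects=True) -> DomainModel:
    gamma = dict(gamma0=-0.019, gamma1=-0.01, gamma2=-0.001)
    re_cov = ((0.35, 0.0), (0.0, 0.006))
    classes = (
        ClassTrajectory(beta0=13.8, beta1=-0.02, beta2=-0.002, re_cov=re_cov,
                        resid_var=0.35, bounds=(0.0, 14.0), **gamma),
        ClassTrajectory(beta0=8.9, beta1=-0.21, beta2=-0.01, re_cov=re_cov,
                        resid_var=0.35, bounds=(0.0, 14.0), **gamma),
    )
    coefs = ((_log(1.17), _log(0.90), _log(0.65), _log(0.49)),) if covariate_effects else ((0, 0, 0, 0),)
    membership = calibrate_membership((0.05,), coefs)
    return DomainModel(membership=membership, classes=classes)


def _participation_domain() -> DomainModel:
    gamma = dict(gamma0=-0.74, gamma1=-0.02, gamma2=-0.002)
    re_cov = ((36.0, 0.0), (0.0, 0.04))
    classes = (
        ClassTrajectory(beta0=110.0, beta1=-0.2, beta2=-0.01, re_cov=re_cov, resid_var=49.0, **gamma),
        ClassTrajectory(beta0=97.0, beta1=-0.55, beta2=-0.02, re_cov=re_cov, resid_var=49.0, **gamma),
    )
    membership = calibrate_membership(
        (0.70,), ((_log(0.99), _log(1.01), _log(0.31), _log(0.14)),)
    )
    return DomainModel(membership=membership, classes=classes)


def _connections_domain(noisy: bool = False) -> DomainModel:
    gamma = dict(gamma0=-0.25, gamma1=0.0, gamma2=-0.001)
    if noisy:
        # deliberately moderate class separation (entropy ~0.65) for
        # exercising the classification-error correction; the age and sex
        # membership effects are set to clearly detectable published magnitudes
        re_cov = ((25.0, 0.0), (0.0, 0.02))
        resid = 25.0
        coefs = ((_log(1.11), _log(1.36), _log(0.64), _log(0.31)),)
    else:
        re_cov = ((16.0, 0.0), (0.0, 0.02))
        resid = 16.0
        coefs = ((_log(0.99), _log(1.36), _log(0.64), _log(0.31)),)
    classes = (
        ClassTrajectory(beta0=104.0, beta1=-0.15, beta2=-0.005, re_cov=re_cov, resid_var=resid, **gamma),
        ClassTrajectory(beta0=90.0, beta1=-0.25, beta2=-0.005, re_cov=re_cov, resid_var=resid, **gamma),
    )
    membership = calibrate_membership((0.29,), coefs)
    return DomainModel(membership=membership, classes=classes)


def _support_domain(covariate_effects=True) -> DomainModel:
    gamma = dict(gamma0=-0.10, gamma1=0.0, gamma2=0.0)
    re_cov = ((12.0, 0.0), (0.0, 0.01))
    classes = (
        ClassTrajectory(beta0=100.8, beta1=-0.05, beta2=-0.005, re_cov=re_cov, resid_var=9.0, **gamma),
        ClassTrajectory(beta0=99.0, beta1=-2.0, beta2=-0.05, re_cov=re_cov, resid_var=9.0, **gamma),
        ClassTrajectory(beta0=86.0, beta1=1.6, beta2=-0.02, re_cov=re_cov, resid_var=9.0, **gamma),
    )
    if covariate_effects:
        coefs = (
            (_log(1.03), _log(1.34), _log(0.85), _log(0.82)),
            (_log(1.08), _log(0.83), _log(1.35), _log(0.38)),
        )
    else:
        coefs = ((0, 0, 0, 0), (0, 0, 0, 0))
    membership = calibrate_membership((0.02, 0.03), coefs)
    return DomainModel(membership=membership, classes=classes)


_OUTCOME_CENTER_SCALE = {
    "cognition": (27.0, 2.5),
    "daily_functioning": (13.0, 1.5),
    "participation": (100.0, 15.0),
    "connections": (100.0, 10.0),
    "support": (100.0, 9.0),
}


def _default_dropout(primary_domain: str) -> DropoutModel:
    center, scale = _OUTCOME_CENTER_SCALE[primary_domain]
    return DropoutModel(
        intercept=float(np.log(0.10 / 0.90)),
        age_coef=0.04,
        outcome_coef=-0.3,
        outcome_domain=primary_domain,
        outcome_center=center,
        outcome_scale=scale,
    )


def available_scenarios() -> tuple:
    return (
        "cognition",
        "daily_functioning",
        "participation",
        "connections",
        "support",
        "joint",
        "attenuation",
    )


def make_scenario(
    name: str,
    n_subjects: int = 2848,
    seed: int = 0,
    dropout: bool = True,
) -> ScenarioConfig:
    """Build one packaged scenario configuration.

    ``dropout=False`` switches off attrition for clean recovery tests;
    everything else about the scenario is fixed by the calibration
    described in the module docstring.
    """
    couplings: tuple = ()
    if name == "cognition":
        models = {"cognition": _cognition_domain()}
    elif name == "daily_functioning":
        models = {"daily_functioning": _daily_functioning_domain()}
    elif name == "participation":
        models = {"participation": _participation_domain()}
    elif name == "connections":
        models = {"connections": _connections_domain()}
    elif name == "attenuation":
        models = {"connections": _connections_domain(noisy=True)}
    elif name == "support":
        models = {"support": _support_domain()}
    elif name == "joint":
        # covariate-free membership keeps the configured couplings exact
        models = {
            "cognition": _cognition_domain(covariate_effects=False),
            "daily_functioning": _daily_functioning_domain(covariate_effects=False),
            "support": _support_domain(covariate_effects=False),
        }
        couplings = (
            Coupling("cognition", 2, "daily_functioning", 2, psi=7.31),
            Coupling(("cognition", "daily_functioning"), (2, 1), "support", 3, psi=4.2),
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {available_scenarios()}")
    primary = next(iter(models))
    return ScenarioConfig(
        n_subjects=n_subjects,
        baseline_age_strata=DEFAULT_AGE_STRATA,
        outcome_models=models,
        sex_prevalence=SEX_PREVALENCE,
        education_distribution=dict(EDUCATION_DISTRIBUTION),
        cross_domain_or=couplings,
        dropout_model=_default_dropout(primary) if dropout else None,
        seed=seed,
        name=name,
    )


def generating_truth(name: str) -> dict:
    """Ground-truth quantities of a packaged scenario (for tests and reports)."""
    cfg = make_scenario(name, dropout=False)
    truth: dict = {"name": name, "domains": {}}
    x, w = _covariate_cells(DEFAULT_AGE_STRATA, SEX_PREVALENCE, EDUCATION_DISTRIBUTION)
    for domain, model in cfg.outcome_models.items():
        p = model.membership.probabilities(x)
        truth["domains"][domain] = {
            "marginal_shares": (w @ p).tolist(),
            "classes": [
                {
                    "beta": (c.beta0, c.beta1, c.beta2),
                    "gamma": (c.gamma0, c.gamma1, c.gamma2),
                }
                for c in model.classes
            ],
        }
    truth["couplings"] = [
        {
            "domain_a": c.domain_a,
            "class_a": c.class_a,
            "domain_b": c.domain_b,
            "class_b": c.class_b,
            "psi": c.psi,
        }
        for c in cfg.cross_domain_or
    ]
    return truth
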