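"""YAML serialization of scenario configurations.

Any scenario built in :mod:`trajmix.scenarios` (or by hand from the
:mod:`trajmix.cohort` dataclasses) round-trips through YAML, so study
conditions can be archived next to the simulated data.  Only the default
age-threshold visit schedule is serializable; configs carrying a custom
schedule callable must be rebuilt in code.
"""

from __future__ import annotations

import yaml

from trajmix.cohort import (
    ClassTrajectory,
    Coupling,
    DomainModel,
    DropoutModel,
    MembershipModel,
    ScenarioConfig,
    default_visit_schedule,
)

__all__ = ["scenario_to_yaml", "scenario_from_yaml", "scenario_to_dict", "scenario_from_dict"]


def _trajectory_dict(t: ClassTrajectory) -> dict:
    return {
        "beta": [float(t.beta0), float(t.beta1), float(t.beta2)],
        "gamma": [float(t.gamma0), float(t.gamma1), float(t.gamma2)],
        "re_cov": [list(map(float, row)) for row in t.re_cov_matrix] if t.re_cov_matrix.size else [],
        "resid_var": float(t.resid_var) if isinstance(t.resid_var, (int, float)) else [float(x) for x in t.resid_var],
        "bounds": [float(x) for x in t.bounds] if t.bounds is not None else None,
    }


def _trajectory_from(d: dict) -> ClassTrajectory:
    b, g = d["beta"], d["gamma"]
    rv = d["resid_var"]
    return ClassTrajectory(
        beta0=b[0], beta1=b[1], beta2=b[2],
        gamma0=g[0], gamma1=g[1], gamma2=g[2],
        re_cov=tuple(tuple(row) for row in d["re_cov"]),
        resid_var=tuple(rv) if isinstance(rv, list) else rv,
        bounds=tuple(d["bounds"]) if d.get("bounds") else None,
    )


def scenario_to_dict(config: ScenarioConfig) -> dict:
    if config.visit_schedule_rule is not default_visit_schedule:
        raise ValueError("only the default visit-schedule rule is serializable")
    return {
        "name": config.name,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "baseline_age_strata": [[float(a), float(w)] for a, w in config.baseline_age_strata],
        "sex_prevalence": config.sex_prevalence,
        "education_distribution": dict(config.education_distribution),
        "exclusion_rates": dict(config.exclusion_rates),
        "outcome_models": {
            domain: {
                "membership": {
                    "intercepts": [float(x) for x in model.membership.intercepts],
                    "coefs": [[float(x) for x in row] for row in model.membership.coefs],
                },
                "classes": [_trajectory_dict(t) for t in model.classes],
            }
            for domain, model in config.outcome_models.items()
        },
        "cross_domain_or": [
            {
                "domain_a": list(c.domain_a) if isinstance(c.domain_a, tuple) else c.domain_a,
                "class_a": list(c.class_a) if isinstance(c.class_a, tuple) else c.class_a,
                "domain_b": c.domain_b,
                "class_b": c.class_b,
                "psi": c.psi,
            }
            for c in config.cross_domain_or
        ],
        "dropout_model": None
        if config.dropout_model is None
        else {
            "intercept": config.dropout_model.intercept,
            "age_coef": config.dropout_model.age_coef,
            "outcome_coef": config.dropout_model.outcome_coef,
            "outcome_domain": config.dropout_model.outcome_domain,
            "outcome_center": config.dropout_model.outcome_center,
            "outcome_scale": config.dropout_model.outcome_scale,
        },
    }


def scenario_from_dict(d: dict) -> ScenarioConfig:
    models = {
        domain: DomainModel(
            membership=MembershipModel(
                intercepts=tuple(m["membership"]["intercepts"]),
                coefs=tuple(tuple(row) for row in m["membership"]["coefs"]),
            ),
            classes=tuple(_trajectory_from(t) for t in m["classes"]),
        )
        for domain, m in d["outcome_models"].items()
    }
    couplings = tuple(
        Coupling(
            domain_a=tuple(c["domain_a"]) if isinstance(c["domain_a"], list) else c["domain_a"],
            class_a=tuple(c["class_a"]) if isinstance(c["class_a"], list) else c["class_a"],
            domain_b=c["domain_b"],
            class_b=c["class_b"],
            psi=c["psi"],
        )
        for c in d.get("cross_domain_or", [])
    )
    dm = d.get("dropout_model")
    return ScenarioConfig(
        n_subjects=d["n_subjects"],
        baseline_age_strata=tuple((a, w) for a, w in d["baseline_age_strata"]),
        outcome_models=models,
        sex_prevalence=d.get("sex_prevalence", 0.63),
        education_distribution=d["education_distribution"],
        cross_domain_or=couplings,
        dropout_model=None if dm is None else DropoutModel(**dm),
        exclusion_rates=d.get("exclusion_rates", {}),
        seed=d.get("seed", 0),
        name=d.get("name", "custom"),
    )


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=False)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
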