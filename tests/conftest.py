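"""Shared fixtures: tiny deterministic cohorts and toy posterior matrices."""

import numpy as np
import pandas as pd
import pytest

from trajmix.cohort import ClassTrajectory, DomainModel, MembershipModel, ScenarioConfig
from trajmix.growth import CohortDesign, GrowthSpec


@pytest.fixture(scope="session")
def two_class_scenario() -> ScenarioConfig:
    """Small, well-separated two-class scenario without dropout or clamping."""
    re_cov = ((1.0, 0.0), (0.0, 0.002))
    classes = (
        ClassTrajectory(beta0=20.0, beta1=-0.1, beta2=-0.01, gamma0=-0.05,
                        re_cov=re_cov, resid_var=1.0),
        ClassTrajectory(beta0=12.0, beta1=-0.6, beta2=-0.02, gamma0=-0.05,
                        re_cov=re_cov, resid_var=1.0),
    )
    membership = MembershipModel(intercepts=(-1.0,), coefs=((0.0, 0.0, 0.0, 0.0),))
    model = DomainModel(membership=membership, classes=classes)
    return ScenarioConfig(
        n_subjects=600,
        baseline_age_strata=((60.0, 0.4), (72.0, 0.3), (81.0, 0.3)),
        outcome_models={"cognition": model},
        seed=42,
    )


@pytest.fixture(scope="session")
def two_class_cohort(two_class_scenario):
    from trajmix.cohort import simulate_cohort

    return simulate_cohort(two_class_scenario, seed=42)


@pytest.fixture(scope="session")
def small_design(two_class_cohort):
    return CohortDesign.from_frame(two_class_cohort, "mmse")


@pytest.fixture
def simple_spec():
    return GrowthSpec(degree=2, age_interactions=True, n_classes=2,
                      random_effects="intercept", random_effects_scope="shared")


@pytest.fixture
def toy_posteriors():
    return np.array(
        [
            [0.9, 0.1],
            [0.8, 0.2],
            [0.5, 0.5],
            [0.2, 0.8],
            [0.1, 0.9],
        ]
    )


def make_long_frame(y_by_subject, times_by_subject, ages):
    """Assemble a minimal long cohort table from per-subject arrays."""
    rows = []
    for sid, (ys, ts, age) in enumerate(zip(y_by_subject, times_by_subject, ages), start=1):
        for y, t in zip(ys, ts):
            rows.append(
                {
                    "id": sid,
                    "wave_time_years": t,
                    "baseline_age": age,
                    "female": 0,
                    "education": "elementary",
                    "mmse": y,
                }
            )
    return pd.DataFrame(rows)
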