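"""Synthetic-cohort generator: schedules, coupling, class assignment, outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from trajmix.cohort import (
    ClassTrajectory,
    ConfigurationError,
    Coupling,
    DomainModel,
    DropoutModel,
    MembershipModel,
    ScenarioConfig,
    assign_classes,
    couple_classes_by_or,
    draw_baseline_roster,
    simulate_cohort,
    simulate_outcome,
)


def _single_domain_config(n, strata, membership, classes, **kw):
    model = DomainModel(membership=membership, classes=classes)
    return ScenarioConfig(
        n_subjects=n, baseline_age_strata=strata, outcome_models={"cognition": model}, **kw
    )


FLAT = ClassTrajectory(beta0=25.0, re_cov=(), resid_var=1.0)
TWO_FLAT = (FLAT, ClassTrajectory(beta0=15.0, re_cov=(), resid_var=1.0))


class TestRoster:
    def test_single_stratum_age_66_gets_six_year_cadence(self):
        cfg = _single_domain_config(
            50, ((66.0, 1.0),), MembershipModel(intercepts=()), (FLAT,), seed=1
        )
        roster = draw_baseline_roster(cfg)
        assert all(tuple(w) == (0.0, 6.0, 12.0) for w in roster["planned_waves"])

    def test_old_cohorts_get_three_year_cadence(self):
        cfg = _single_domain_config(
            50, ((81.0, 1.0),), MembershipModel(intercepts=()), (FLAT,), seed=1
        )
        roster = draw_baseline_roster(cfg)
        assert all(tuple(w) == (0.0, 3.0, 6.0, 9.0, 12.0) for w in roster["planned_waves"])

    def test_zero_subjects_forbidden(self):
        with pytest.raises(ConfigurationError):
            _single_domain_config(0, ((66.0, 1.0),), MembershipModel(intercepts=()), (FLAT,))

    def test_empty_strata_forbidden(self):
        with pytest.raises(ConfigurationError):
            _single_domain_config(5, (), MembershipModel(intercepts=()), (FLAT,))

    def test_stratum_shares_match_weights(self):
        # binomial oracle: empirical share of the age-81 stratum within 3 SE of 0.5
        cfg = _single_domain_config(
            10_000, ((60.0, 0.5), (81.0, 0.5)), MembershipModel(intercepts=()), (FLAT,), seed=7
        )
        roster = draw_baseline_roster(cfg)
        share = (roster["baseline_age"] == 81.0).mean()
        se = np.sqrt(0.25 / 10_000)
        assert abs(share - 0.5) < 3 * se

    def test_roster_deterministic_given_seed(self):
        cfg = _single_domain_config(
            200, ((60.0, 0.5), (81.0, 0.5)), MembershipModel(intercepts=()), (FLAT,), seed=3
        )
        r1 = draw_baseline_roster(cfg)
        r2 = draw_baseline_roster(cfg)
        pd.testing.assert_frame_equal(r1, r2)


class TestCoupling:
    def test_independence(self):
        cells = couple_classes_by_or(0.1, 0.2, 1.0)
        assert cells[1, 1] == pytest.approx(0.02, abs=1e-12)

    def test_matches_bisection_oracle(self):
        # independent 1-D root search on the OR constraint in the (1,1) cell
        p, q, psi = 0.09, 0.05, 7.3

        def or_of(p11):
            return (p11 * (1 - p - q + p11)) / ((p - p11) * (q - p11)) - psi

        p11_oracle = brentq(or_of, p * q, min(p, q) - 1e-12, xtol=1e-14)
        cells = couple_classes_by_or(p, q, psi)
        assert cells[1, 1] == pytest.approx(p11_oracle, abs=1e-10)

    @pytest.mark.parametrize("p,q,psi", [(0.1, 0.2, 3.0), (0.5, 0.5, 0.2), (0.03, 0.07, 4.2)])
    def test_self_consistency(self, p, q, psi):
        cells = couple_classes_by_or(p, q, psi)
        assert cells.sum() == pytest.approx(1.0, abs=1e-12)
        assert cells[1].sum() == pytest.approx(p, abs=1e-12)
        assert cells[:, 1].sum() == pytest.approx(q, abs=1e-12)
        recovered = cells[1, 1] * cells[0, 0] / (cells[1, 0] * cells[0, 1])
        assert recovered == pytest.approx(psi, abs=1e-8)

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            couple_classes_by_or(0.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            couple_classes_by_or(0.5, 0.5, -1.0)


class TestAssignClasses:
    def test_symmetric_membership_splits_evenly(self):
        membership = MembershipModel(intercepts=(0.0,), coefs=((0, 0, 0, 0),))
        cfg = _single_domain_config(
            10_000, ((66.0, 1.0),), membership, TWO_FLAT, seed=11
        )
        roster = assign_classes(draw_baseline_roster(cfg), cfg)
        share = (roster["true_class_cognition"] == 2).mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_age_effect_recovered_by_logistic_oracle(self):
        # generating log-OR ln(1.11) per year of baseline age, refit on true labels
        import statsmodels.api as sm

        beta_age = np.log(1.11)
        membership = MembershipModel(intercepts=(-1.0,), coefs=((beta_age, 0, 0, 0),))
        cfg = _single_domain_config(
            10_000, ((60.0, 0.4), (72.0, 0.3), (84.0, 0.3)), membership, TWO_FLAT, seed=13
        )
        roster = assign_classes(draw_baseline_roster(cfg), cfg)
        y = (roster["true_class_cognition"] == 2).astype(float)
        X = sm.add_constant(roster["baseline_age"] - 60.0)
        fit = sm.Logit(y, X).fit(disp=0)
        est, se = fit.params.iloc[1], fit.bse.iloc[1]
        assert abs(est - beta_age) < 2.5 * se

    def test_pairwise_coupling_hits_target_or(self):
        # contingency-table oracle at n=10,000
        m1 = MembershipModel(intercepts=(-2.0,), coefs=((0, 0, 0, 0),))
        m2 = MembershipModel(intercepts=(-2.5,), coefs=((0, 0, 0, 0),))
        models = {
            "cognition": DomainModel(membership=m1, classes=TWO_FLAT),
            "daily_functioning": DomainModel(membership=m2, classes=TWO_FLAT),
        }
        cfg = ScenarioConfig(
            n_subjects=10_000,
            baseline_age_strata=((66.0, 1.0),),
            outcome_models=models,
            cross_domain_or=(Coupling("cognition", 2, "daily_functioning", 2, psi=7.3),),
            seed=17,
        )
        roster = assign_classes(draw_baseline_roster(cfg), cfg)
        a = (roster["true_class_cognition"] == 2).to_numpy()
        b = (roster["true_class_daily_functioning"] == 2).to_numpy()
        n11, n10 = (a & b).sum(), (a & ~b).sum()
        n01, n00 = (~a & b).sum(), (~a & ~b).sum()
        log_or = np.log(n11 * n00 / (n10 * n01))
        se = np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
        assert abs(log_or - np.log(7.3)) < 2.5 * se

    def test_unknown_coupled_domain_rejected(self):
        m1 = MembershipModel(intercepts=(-2.0,), coefs=((0, 0, 0, 0),))
        with pytest.raises(ConfigurationError):
            ScenarioConfig(
                n_subjects=10,
                baseline_age_strata=((66.0, 1.0),),
                outcome_models={"cognition": DomainModel(membership=m1, classes=TWO_FLAT)},
                cross_domain_or=(Coupling("cognition", 2, "nonexistent", 2, psi=2.0),),
            )


class TestSimulateOutcome:
    def test_noise_free_limit_reproduces_polynomial(self):
        traj = ClassTrajectory(beta0=20.0, beta1=-0.5, beta2=-0.02, gamma0=-0.1,
                               gamma1=0.01, gamma2=0.0, re_cov=(), resid_var=1e-18)
        rng = np.random.default_rng(0)
        t = np.array([0.0, 3.0, 6.0])
        vals = simulate_outcome(np.array([10.0]), t, traj, rng)[0]
        a = 10.0
        expected = (20.0 - 0.1 * a) + (-0.5 + 0.01 * a) * t + (-0.02) * t**2
        np.testing.assert_allclose(vals, expected, atol=1e-6)

    def test_printed_age_gradient_on_intercept(self):
        # a 0.045-point drop per year of baseline age: 30 - 0.045*20 = 29.1
        traj = ClassTrajectory(beta0=30.0, gamma0=-0.045, re_cov=(), resid_var=1e-18)
        rng = np.random.default_rng(0)
        vals = simulate_outcome(np.array([20.0]), (0.0, 6.0, 12.0), traj, rng)[0]
        np.testing.assert_allclose(vals, 29.1, atol=1e-6)

    def test_sample_mean_matches_analytic_moments(self):
        # analytic mean of the linear mixed model at t=3 within 3 SE
        traj = ClassTrajectory(beta0=10.0, beta1=0.5, beta2=-0.05,
                               re_cov=((2.0, 0.1), (0.1, 0.05)), resid_var=1.5)
        rng = np.random.default_rng(5)
        n = 10_000
        t = np.array([3.0])
        vals = simulate_outcome(np.zeros(n), t, traj, rng)[:, 0]
        mean_true = 10.0 + 0.5 * 3 - 0.05 * 9
        var_true = 2.0 + 2 * 3 * 0.1 + 9 * 0.05 + 1.5  # Z Psi Z' + sigma2
        assert abs(vals.mean() - mean_true) < 3 * np.sqrt(var_true / n)
        assert abs(vals.var() - var_true) < 4 * var_true * np.sqrt(2 / n)

    def test_bounds_are_clamped(self):
        traj = ClassTrajectory(beta0=29.5, re_cov=(), resid_var=4.0, bounds=(0.0, 30.0))
        rng = np.random.default_rng(1)
        vals = simulate_outcome(np.zeros(500), (0.0,), traj, rng)
        assert vals.max() <= 30.0

    def test_empty_waves_rejected(self):
        with pytest.raises(ValueError):
            simulate_outcome(np.zeros(1), (), FLAT, np.random.default_rng(0))


class TestSimulateCohort:
    def test_no_dropout_keeps_all_planned_waves(self, two_class_scenario):
        df = simulate_cohort(two_class_scenario, seed=1)
        counts = df.groupby("id").size()
        base = df.drop_duplicates("id").set_index("id")
        expected = base["baseline_age"].map(lambda a: 5 if a >= 78 else 3)
        assert (counts == expected).all()

    def test_fixed_seed_reproduces_table_exactly(self, two_class_scenario):
        d1 = simulate_cohort(two_class_scenario, seed=9)
        d2 = simulate_cohort(two_class_scenario, seed=9)
        assert d1.to_csv(index=False) == d2.to_csv(index=False)

    def test_dropout_is_monotone(self, two_class_scenario):
        cfg = two_class_scenario.replace(
            dropout_model=DropoutModel(intercept=-1.0, age_coef=0.05,
                                       outcome_coef=-0.2, outcome_domain="cognition",
                                       outcome_center=20.0, outcome_scale=3.0)
        )
        df = simulate_cohort(cfg, seed=2)
        for _, sub in df.groupby("id"):
            times = np.sort(sub["wave_time_years"].to_numpy())
            planned = (0.0, 3.0, 6.0, 9.0, 12.0) if sub["baseline_age"].iloc[0] >= 78 else (0.0, 6.0, 12.0)
            assert tuple(times) == planned[: len(times)]
            assert times[0] == 0.0

    def test_packaged_cognition_scenario_class_share(self):
        from trajmix.scenarios import make_scenario

        cfg = make_scenario("cognition", n_subjects=2848, seed=5)
        df = simulate_cohort(cfg)
        share = (df.drop_duplicates("id")["true_class_cognition"] == 2).mean()
        se = np.sqrt(0.09 * 0.91 / 2848)
        assert abs(share - 0.09) < 3 * se
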