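"""EM machinery: marginal moments, likelihood oracles, ascent, recovery."""

import numpy as np
import pytest

from trajmix.growth import (
    CohortDesign,
    GrowthSpec,
    MixtureParams,
    NumericalError,
    class_conditional_marginal,
    e_step,
    fit_em,
    loglik,
    m_step,
    params_from_responsibilities,
    random_start_fit,
    simulate_design,
)
from trajmix.growth import _mixture_loglik

from conftest import make_long_frame


def _params(pi, beta, psi, sigma2):
    return MixtureParams(pi=np.asarray(pi), beta=np.asarray(beta),
                         psi=np.asarray(psi), sigma2=np.asarray(sigma2))


class TestClassConditionalMarginal:
    def test_no_random_effects_gives_diagonal_covariance(self):
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="none")
        p = _params([1.0], [[10.0, -0.5]], np.zeros((1, 0, 0)), np.full(5, 2.0))
        m, V = class_conditional_marginal([0.0, 6.0, 12.0], 60.0, p, 0, spec)
        np.testing.assert_allclose(m, [10.0, 7.0, 4.0])
        np.testing.assert_allclose(V, np.diag([2.0, 2.0, 2.0]))

    def test_single_wave_intercept_re_variance(self):
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="intercept")
        p = _params([1.0], [[10.0, 0.0]], [[[3.0]]], np.full(5, 2.0))
        _, V = class_conditional_marginal([0.0], 70.0, p, 0, spec)
        assert V[0, 0] == pytest.approx(3.0 + 2.0)

    def test_two_wave_hand_expansion(self):
        # symbolic expansion of Z Psi Z' + sigma2 I for Z = [[1, 0], [1, 6]]
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1,
                          random_effects="intercept_slope")
        psi = np.array([[2.0, 0.3], [0.3, 0.1]])
        p = _params([1.0], [[5.0, 1.0]], psi[None], np.full(5, 1.5))
        _, V = class_conditional_marginal([0.0, 6.0], 60.0, p, 0, spec)
        expected = np.array(
            [
                [2.0 + 1.5, 2.0 + 6 * 0.3],
                [2.0 + 6 * 0.3, 2.0 + 12 * 0.3 + 36 * 0.1 + 1.5],
            ]
        )
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_age_interaction_shifts_mean(self):
        spec = GrowthSpec(degree=2, age_interactions=True, n_classes=1, random_effects="none")
        beta = [[20.0, -0.5, 0.01, -0.05, -0.01, 0.001]]
        p = _params([1.0], beta, np.zeros((1, 0, 0)), np.full(5, 1.0))
        a = 15.0
        t = np.array([0.0, 3.0])
        m, _ = class_conditional_marginal(t, 60.0 + a, p, 0, spec)
        expected = (20 - 0.05 * a) + (-0.5 - 0.01 * a) * t + (0.01 + 0.001 * a) * t**2
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_empty_waves_rejected(self):
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="none")
        p = _params([1.0], [[1.0, 0.0]], np.zeros((1, 0, 0)), np.full(5, 1.0))
        with pytest.raises(ValueError):
            class_conditional_marginal([], 60.0, p, 0, spec)


class TestLoglik:
    def test_single_subject_single_wave_gaussian_density(self):
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="intercept")
        v = 3.0 + 1.0  # psi + sigma2
        p = _params([1.0], [[8.0, 0.0]], [[[3.0]]], np.full(5, 1.0))
        df = make_long_frame([[8.0]], [[0.0]], [60.0])  # y equals the mean
        design = CohortDesign.from_frame(df, "mmse")
        assert loglik(design, p, spec) == pytest.approx(-0.5 * np.log(2 * np.pi * v), abs=1e-12)

    def test_matches_gauss_hermite_oracle(self):
        # brute-force integration over the random intercept, 50 nodes
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="intercept")
        psi, sig = 2.5, 1.2
        beta = np.array([[10.0, -0.8]])
        p = _params([1.0], beta, [[[psi]]], np.full(5, sig))
        times = [0.0, 6.0]
        y = np.array([11.0, 4.5])
        df = make_long_frame([y], [times], [60.0])
        design = CohortDesign.from_frame(df, "mmse")

        nodes, weights = np.polynomial.hermite_e.hermegauss(50)
        m = beta[0, 0] + beta[0, 1] * np.asarray(times)
        dens = 0.0
        for z, w in zip(nodes, weights):
            b = np.sqrt(psi) * z
            dens += w * np.prod(
                np.exp(-0.5 * (y - m - b) ** 2 / sig) / np.sqrt(2 * np.pi * sig)
            )
        oracle = np.log(dens / np.sqrt(2 * np.pi))
        assert loglik(design, p, spec) == pytest.approx(oracle, abs=1e-6)

    def test_duplicate_classes_collapse_to_single_class(self):
        spec1 = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="intercept")
        spec2 = GrowthSpec(degree=1, age_interactions=False, n_classes=2, random_effects="intercept")
        df = make_long_frame([[9.0, 5.0], [10.0, 8.0]], [[0.0, 6.0], [0.0, 6.0]], [60.0, 70.0])
        design = CohortDesign.from_frame(df, "mmse")
        p1 = _params([1.0], [[10.0, -0.5]], [[[2.0]]], np.full(5, 1.0))
        p2 = _params([0.5, 0.5], [[10.0, -0.5], [10.0, -0.5]],
                     [[[2.0]], [[2.0]]], np.full(5, 1.0))
        assert loglik(design, p2, spec2) == pytest.approx(loglik(design, p1, spec1), abs=1e-10)

    def test_loglik_is_sum_of_subject_contributions(self, small_design, simple_spec):
        # observed-entries independence: deleting a subject removes exactly
        # that subject's contribution
        resp = np.column_stack([np.ones(small_design.n_subjects) * 0.6,
                                np.ones(small_design.n_subjects) * 0.4])
        p = params_from_responsibilities(small_design, resp, simple_spec)
        from trajmix.growth import _group_gaussians

        logphi, _ = _group_gaussians(small_design, p, simple_spec)
        total, _ = _mixture_loglik(logphi, p.pi)
        per_subject = np.logaddexp(
            np.log(p.pi[0]) + logphi[:, 0], np.log(p.pi[1]) + logphi[:, 1]
        )
        assert total == pytest.approx(per_subject.sum(), abs=1e-8)


class TestESteps:
    def test_single_class_posterior_is_one(self, small_design):
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1, random_effects="intercept")
        resp = np.ones((small_design.n_subjects, 1))
        p = params_from_responsibilities(small_design, resp, spec)
        post, _ = e_step(small_design, p, spec)
        np.testing.assert_allclose(post, 1.0)

    def test_hand_bayes_rule(self):
        # class densities (0.2, 0.1) with priors (0.3, 0.7)
        logphi = np.log(np.array([[0.2, 0.1]]))
        _, post = _mixture_loglik(logphi, np.array([0.3, 0.7]))
        np.testing.assert_allclose(post[0], [0.06 / 0.13, 0.07 / 0.13], atol=1e-12)

    def test_equal_densities_equal_priors_give_half(self):
        logphi = np.log(np.array([[0.4, 0.4]]))
        _, post = _mixture_loglik(logphi, np.array([0.5, 0.5]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-14)

    def test_zero_density_raises(self):
        logphi = np.array([[-np.inf, -np.inf]])
        with pytest.raises(NumericalError):
            _mixture_loglik(logphi, np.array([0.5, 0.5]))


class TestMStep:
    def test_mixing_proportions_are_posterior_column_means(self, small_design, simple_spec):
        rng = np.random.default_rng(0)
        post = rng.dirichlet((1, 1), size=small_design.n_subjects)
        init = params_from_responsibilities(small_design, post, simple_spec)
        new, _ = m_step(small_design, post, init, simple_spec)
        np.testing.assert_allclose(new.pi, post.mean(axis=0), atol=1e-12)

    def test_single_m_step_does_not_decrease_loglik(self, small_design, simple_spec):
        rng = np.random.default_rng(1)
        post = rng.dirichlet((1, 1), size=small_design.n_subjects)
        params = params_from_responsibilities(small_design, post, simple_spec)
        ll0 = loglik(small_design, params, simple_spec)
        post1, _ = e_step(small_design, params, simple_spec)
        new, _ = m_step(small_design, post1, params, simple_spec)
        ll1 = loglik(small_design, new, simple_spec)
        assert ll1 >= ll0 - 1e-8

    def test_degenerate_partition_recovers_per_class_ols(self):
        # noise-free data from two polynomial curves, hard posteriors:
        # the fixed effects must equal the per-class OLS fits exactly
        spec = GrowthSpec(degree=2, age_interactions=False, n_classes=2, random_effects="none")
        t = [0.0, 3.0, 6.0, 9.0, 12.0]
        tt = np.asarray(t)
        y1 = 20.0 - 0.5 * tt + 0.01 * tt**2
        y2 = 10.0 - 1.0 * tt - 0.02 * tt**2
        df = make_long_frame([y1, y1, y2, y2], [t] * 4, [80.0] * 4)
        design = CohortDesign.from_frame(df, "mmse")
        post = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        init = params_from_responsibilities(design, post, spec)
        new, _ = m_step(design, post, init, spec)
        np.testing.assert_allclose(new.beta[0], [20.0, -0.5, 0.01], atol=1e-6)
        np.testing.assert_allclose(new.beta[1], [10.0, -1.0, -0.02], atol=1e-6)


class TestFitEM:
    def test_huge_tolerance_returns_after_one_iteration(self, small_design, simple_spec):
        rng = np.random.default_rng(2)
        post = rng.dirichlet((1, 1), size=small_design.n_subjects)
        init = params_from_responsibilities(small_design, post, simple_spec)
        fit = fit_em(small_design, simple_spec, init, tol=1e6)
        assert fit.converged and fit.n_iterations == 1

    def test_loglik_trace_is_monotone(self, small_design, simple_spec):
        rng = np.random.default_rng(3)
        post = rng.dirichlet((1, 1), size=small_design.n_subjects)
        init = params_from_responsibilities(small_design, post, simple_spec)
        fit = fit_em(small_design, simple_spec, init, tol=1e-8, max_iter=100)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_two_class_recovery_on_separated_data(self, small_design):
        spec = GrowthSpec(degree=2, age_interactions=True, n_classes=2,
                          random_effects="intercept_slope")
        fit = random_start_fit(small_design, spec, n_starts=8, n_init_iter=8,
                               n_final=2, seed=0)
        # canonical order: class 1 has the higher intercept (truth 20 vs 12)
        assert abs(fit.params.beta[0, 0] - 20.0) < 0.4
        assert abs(fit.params.beta[1, 0] - 12.0) < 0.8
        truth_share = 1 / (1 + np.exp(1.0))  # membership logit intercept -1
        assert abs(fit.params.pi[1] - truth_share) < 3 * np.sqrt(truth_share * (1 - truth_share) / 600)

    def test_single_class_matches_direct_mixed_model_ml(self):
        # independent oracle: statsmodels MixedLM maximizes the same
        # marginal likelihood for the K=1 random-intercept-slope model
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 60
        rows = []
        for i in range(n):
            t = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
            b = rng.multivariate_normal([0, 0], [[2.0, 0.1], [0.1, 0.05]])
            y = 15.0 - 0.4 * t + b[0] + b[1] * t + rng.normal(0, 1.0, t.size)
            rows.append((y, t))
        df = make_long_frame([r[0] for r in rows], [r[1] for r in rows], [60.0] * n)
        spec = GrowthSpec(degree=1, age_interactions=False, n_classes=1,
                          random_effects="intercept_slope")
        design = CohortDesign.from_frame(df, "mmse")
        fit = random_start_fit(design, spec, n_starts=1, n_init_iter=10, n_final=1,
                               seed=0, tol=1e-10, max_iter=2000)
        md = sm.MixedLM.from_formula(
            "mmse ~ wave_time_years", df, groups=df["id"],
            re_formula="~wave_time_years",
        )
        oracle = md.fit(reml=False, method="lbfgs", maxiter=500)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)


class TestRandomStarts:
    def test_fixed_seed_reproduces_best_loglik(self, small_design, simple_spec):
        f1 = random_start_fit(small_design, simple_spec, n_starts=5, n_init_iter=5,
                              n_final=2, seed=4)
        f2 = random_start_fit(small_design, simple_spec, n_starts=5, n_init_iter=5,
                              n_final=2, seed=4)
        assert f1.loglik == f2.loglik

    def test_more_starts_never_find_worse_optimum(self, small_design, simple_spec):
        few = random_start_fit(small_design, simple_spec, n_starts=2, n_init_iter=5,
                               n_final=1, seed=5)
        many = random_start_fit(small_design, simple_spec, n_starts=10, n_init_iter=5,
                                n_final=3, seed=5)
        assert many.loglik >= few.loglik - 1e-6

    def test_zero_starts_rejected(self, small_design, simple_spec):
        with pytest.raises(ValueError):
            random_start_fit(small_design, simple_spec, n_starts=0)


class TestMissingData:
    def test_deleting_a_wave_changes_only_that_subjects_contribution(self, simple_spec):
        t = [0.0, 3.0, 6.0, 9.0, 12.0]
        rng = np.random.default_rng(9)
        ys = [18 - 0.4 * np.asarray(t) + rng.normal(0, 1, 5) for _ in range(6)]
        df_full = make_long_frame(ys, [t] * 6, [65.0] * 6)
        df_del = df_full.drop(df_full[(df_full["id"] == 3) & (df_full["wave_time_years"] == 6.0)].index)
        design_full = CohortDesign.from_frame(df_full, "mmse")
        design_del = CohortDesign.from_frame(df_del, "mmse")
        resp = np.column_stack([np.full(6, 0.7), np.full(6, 0.3)])
        p = params_from_responsibilities(design_full, resp, simple_spec)

        def subject_ll(design, sid):
            from trajmix.growth import _group_gaussians

            logphi, _ = _group_gaussians(design, p, simple_spec)
            i = list(design.subject_ids).index(sid)
            return np.logaddexp(np.log(p.pi[0]) + logphi[i, 0], np.log(p.pi[1]) + logphi[i, 1])

        ll_full = loglik(design_full, p, simple_spec)
        ll_del = loglik(design_del, p, simple_spec)
        delta_direct = subject_ll(design_full, 3) - subject_ll(design_del, 3)
        assert ll_full - ll_del == pytest.approx(delta_direct, abs=1e-8)


class TestSimulateDesign:
    def test_preserves_patterns_and_changes_values(self, small_design, simple_spec):
        resp = np.column_stack([np.full(small_design.n_subjects, 0.5)] * 2)
        p = params_from_responsibilities(small_design, resp, simple_spec)
        sim = simulate_design(small_design, p, simple_spec, np.random.default_rng(0))
        assert sim.n_subjects == small_design.n_subjects
        for g_old, g_new in zip(small_design.groups, sim.groups):
            np.testing.assert_array_equal(g_old["wave_idx"], g_new["wave_idx"])
            assert g_old["y"].shape == g_new["y"].shape
            assert not np.allclose(g_old["y"], g_new["y"])
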