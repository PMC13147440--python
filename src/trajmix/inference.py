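"""Post-fit inference on latent trajectory classes.

Latent class membership is never observed, so downstream association
analyses must correct for classification error.  Two strategies are
implemented:

* a maximum-likelihood three-step correction for covariate–class
  regressions: the modal assignment is treated as an indicator of the
  latent class measured with the known error rates estimated from the
  posterior matrix, and the covariate multinomial logit is fitted to the
  latent variable rather than the noisy indicator;
* pseudo-class multiple imputation for cross-domain concordance: class
  labels are repeatedly drawn from each subject's posterior distribution,
  the analysis (a pairwise odds ratio, a group comparison test) is run
  per draw, and results are combined with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from trajmix.cohort import AGE_CENTER
from trajmix.pooling import PooledEstimate, pool_estimates, pool_pvalues

__all__ = [
    "classification_error_matrix",
    "three_step_covariate_model",
    "ThreeStepResult",
    "pseudo_class_draw",
    "pairwise_concordance_or",
    "concordance_groups",
    "ConcordanceGroups",
    "CONCORDANCE_LABELS",
    "group_profile_table",
]


def classification_error_matrix(posteriors: np.ndarray) -> np.ndarray:
    """Modal-assignment error rates ``D[k, s] = P(modal = s | true class = k)``.

    Estimated from the posterior matrix as the posterior-mass-weighted
    cross-tabulation of modal against latent class; rows sum to one.
    """
    post = np.asarray(posteriors, dtype=float)
    n, k = post.shape
    if k < 2:
        raise ValueError("classification error is defined for K >= 2 only")
    modal = post.argmax(axis=1)
    mass = post.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("a latent class carries no posterior mass")
    d = np.zeros((k, k))
    for s in range(k):
        d[:, s] = post[modal == s].sum(axis=0)
    return d / mass[:, None]


def _design_from_covariates(covariates: pd.DataFrame):
    """Covariate design (intercept, centred age, female, education dummies)."""
    df = covariates
    cols, names = [np.ones(len(df))], ["intercept"]
    if "baseline_age" in df.columns:
        cols.append(df["baseline_age"].to_numpy(dtype=float) - AGE_CENTER)
        names.append("baseline_age")
    if "female" in df.columns:
        cols.append(df["female"].to_numpy(dtype=float))
        names.append("female")
    if "education" in df.columns:
        edu = df["education"].astype(str).to_numpy()
        cols.append((edu == "high_school").astype(float))
        cols.append((edu == "university").astype(float))
        names.extend(["edu_high_school", "edu_university"])
    return np.column_stack(cols), names


@dataclass
class ThreeStepResult:
    """Corrected covariate–class multinomial logit."""

    coef: np.ndarray  # (K-1, p) log-odds, class 1 reference
    se: np.ndarray
    coef_names: list
    n_classes: int
    loglik: float
    n_dropped: int
    error_matrix: np.ndarray
    separation: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        zc = stats.norm.ppf(0.5 + level / 2.0)
        rows = []
        for k in range(self.coef.shape[0]):
            for j, name in enumerate(self.coef_names):
                sep = bool(self.separation[k, j]) if self.separation.size else False
                rows.append(
                    {
                        "contrast": f"class {k + 2} vs class 1",
                        "term": name,
                        "log_or": self.coef[k, j],
                        "se": self.se[k, j],
                        "or": np.exp(self.coef[k, j]),
                        "or_lo": 0.0 if sep else np.exp(self.coef[k, j] - zc * self.se[k, j]),
                        "or_hi": np.inf if sep else np.exp(self.coef[k, j] + zc * self.se[k, j]),
                        "separation": sep,
                    }
                )
        return pd.DataFrame(rows)


def three_step_covariate_model(
    posteriors: np.ndarray,
    covariates: pd.DataFrame,
    error_matrix: np.ndarray | None = None,
) -> ThreeStepResult:
    """Covariate association with latent class, corrected for assignment error.

    Step 1 is the existing mixture fit (supplying ``posteriors``); step 2
    computes the modal assignment and its classification-error matrix D;
    step 3 fits a multinomial logit of the *latent* class on covariates by
    maximizing ``sum_i log sum_k P(k | x_i; theta) D[k, s_i]`` with D held
    fixed — the maximum-likelihood (ML) three-step estimator.  Passing the
    identity matrix as ``error_matrix`` recovers the naive regression on
    modal assignments.  Rows with missing covariates are dropped and
    counted.  Wald standard errors come from the observed information;
    coefficients beyond ±10 are flagged as separation with infinite CIs.
    """
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    mask = ~covariates.isna().any(axis=1).to_numpy()
    n_dropped = int((~mask).sum())
    X, names = _design_from_covariates(covariates.loc[mask])
    s = post[mask].argmax(axis=1)
    D = classification_error_matrix(post) if error_matrix is None else np.asarray(error_matrix, float)
    logD = np.log(np.clip(D, 1e-12, 1.0))  # (K, K); column s_i enters subject i
    logD_i = logD[:, s].T  # (n, K)
    p = X.shape[1]

    def unpack(theta):
        return theta.reshape(K - 1, p)

    def neg_loglik_grad(theta):
        B = unpack(theta)
        eta = np.concatenate([np.zeros((X.shape[0], 1)), X @ B.T], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        logP = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
        a = logP + logD_i
        amax = a.max(axis=1, keepdims=True)
        ll_i = amax.ravel() + np.log(np.exp(a - amax).sum(axis=1))
        w = np.exp(a - ll_i[:, None])  # posterior over latent class given (x, s)
        P = np.exp(logP)
        g = ((w - P)[:, 1:, None] * X[:, None, :]).sum(axis=0)
        return -ll_i.sum(), -g.ravel()

    theta0 = np.zeros((K - 1) * p)
    res = optimize.minimize(neg_loglik_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x

    # observed information via central differences of the analytic gradient
    h = 1e-5
    dim = theta.size
    H = np.zeros((dim, dim))
    for j in range(dim):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = neg_loglik_grad(tp)
        _, gm = neg_loglik_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(K - 1, p)
    except np.linalg.LinAlgError:
        se = np.full((K - 1, p), np.nan)
    coef = unpack(theta)
    separation = np.abs(coef) > 10.0
    return ThreeStepResult(
        coef=coef,
        se=se,
        coef_names=names,
        n_classes=K,
        loglik=float(-res.fun),
        n_dropped=n_dropped,
        error_matrix=D,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# pseudo-class machinery


def pseudo_class_draw(posteriors: np.ndarray, m: int = 20, seed: int | None = None) -> np.ndarray:
    """Draw ``m`` complete class assignments from the posterior matrix.

    Returns an (m, N) array of 1-based labels; each imputation samples
    every subject's class independently from their posterior row.
    """
    post = np.asarray(posteriors, dtype=float)
    rng = np.random.default_rng(seed)
    n, k = post.shape
    cum = post.cumsum(axis=1)
    cum /= cum[:, -1:]
    u = rng.random((m, n))
    return 1 + (u[:, :, None] > cum[None, :, :]).sum(axis=2)


def _log_or_2x2(a: np.ndarray, b: np.ndarray):
    """MLE log odds ratio and variance of two binary vectors.

    Equals the coefficient of the saturated logistic regression of either
    indicator on the other (the 2x2 MLE is symmetric in direction).
    Applies the Haldane–Anscombe 0.5 correction when a cell is empty and
    flags the draw.
    """
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    cells = np.array([n11, n10, n01, n00])
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    log_or = np.log(n11 * n00 / (n10 * n01))
    var = 1.0 / n11 + 1.0 / n10 + 1.0 / n01 + 1.0 / n00
    return log_or, var, corrected


def pairwise_concordance_or(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
    target_a: int = 2,
    target_b: int = 2,
    df_com: float = np.inf,
) -> PooledEstimate:
    """Pooled pseudo-class odds ratio between two class indicators.

    Per imputation, the log odds ratio between ``1{A = target_a}`` and
    ``1{B = target_b}`` is the saturated logistic-regression estimate
    (identical in both regression directions); estimates are pooled with
    Rubin's rules and returned on the odds-ratio scale.  Imputations with
    an empty cell use the Haldane–Anscombe correction; if more than half
    need it, the pairing is considered unstable and an error is raised.
    """
    A = np.atleast_2d(draws_a)
    B = np.atleast_2d(draws_b)
    if A.shape != B.shape:
        raise ValueError("draw matrices must have matching shape (m, N)")
    ests, vars_, flagged = [], [], 0
    for j in range(A.shape[0]):
        lo, v, corrected = _log_or_2x2((A[j] == target_a).astype(int), (B[j] == target_b).astype(int))
        flagged += corrected
        ests.append(lo)
        vars_.append(v)
    if flagged > 0.5 * A.shape[0]:
        raise RuntimeError(f"{flagged}/{A.shape[0]} imputations had empty cells")
    return pool_estimates(ests, vars_, exponentiate=True, df_com=df_com)


CONCORDANCE_LABELS = (
    "concordant_high",
    "concordant_low",
    "discordant_highcog_lowfunc",
    "discordant_lowcog_highfunc",
)


@dataclass
class ConcordanceGroups:
    """Four-way cognition x daily-functioning concordance classification.

    Class 1 is the preserved/stable trajectory in both domains, class 2
    the declining one; the cross-classification yields two concordant and
    two discordant patterns, per pseudo-class imputation and for the
    modal assignment.
    """

    draws: np.ndarray  # (m, N) of label indices into CONCORDANCE_LABELS
    modal: np.ndarray  # (N,) label indices

    def labels(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(CONCORDANCE_LABELS)[idx]

    @property
    def modal_labels(self) -> np.ndarray:
        return self.labels(self.modal)

    def shares(self) -> dict:
        n = self.modal.size
        return {
            lab: float(np.mean(self.modal == i)) for i, lab in enumerate(CONCORDANCE_LABELS)
        }


def _cross_classify(cog: np.ndarray, func: np.ndarray) -> np.ndarray:
    out = np.empty(cog.shape, dtype=int)
    out[(cog == 1) & (func == 1)] = 0
    out[(cog == 2) & (func == 2)] = 1
    out[(cog == 1) & (func == 2)] = 2
    out[(cog == 2) & (func == 1)] = 3
    return out


def concordance_groups(
    posterior_cog: np.ndarray,
    posterior_func: np.ndarray,
    m: int = 20,
    seed: int | None = None,
) -> ConcordanceGroups:
    """Cross-classify cognition and daily-functioning class assignments.

    Produces the four-group classification per pseudo-class imputation
    (both domains drawn with a shared seed stream) and for the modal
    assignment.  Both posterior matrices must cover the same subjects in
    the same order.
    """
    pc = np.asarray(posterior_cog, dtype=float)
    pf = np.asarray(posterior_func, dtype=float)
    if pc.shape[0] != pf.shape[0]:
        raise ValueError("posterior matrices must cover the same subjects")
    ss = np.random.SeedSequence(seed)
    s_cog, s_func = ss.spawn(2)
    draws_cog = pseudo_class_draw(pc, m=m, seed=s_cog)
    draws_func = pseudo_class_draw(pf, m=m, seed=s_func)
    draws = _cross_classify(draws_cog, draws_func)
    modal = _cross_classify(pc.argmax(axis=1) + 1, pf.argmax(axis=1) + 1)
    return ConcordanceGroups(draws=draws, modal=modal)


# ---------------------------------------------------------------------------
# profile table


def _chi2_pvalue(table: np.ndarray, rng: np.random.Generator, mc_replications: int = 2000) -> float:
    """Chi-square p-value; Monte Carlo reference when expected counts are sparse."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan
    r, c = table.sum(axis=1), table.sum(axis=0)
    expected = np.outer(r, c) / table.sum()
    if expected.min() >= 5:
        return float(stats.chi2_contingency(table, correction=False)[1])
    stat_obs = float(((table - expected) ** 2 / expected).sum())
    sampler = stats.random_table(r.astype(int), c.astype(int))
    sims = sampler.rvs(mc_replications, random_state=rng)
    stats_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1.0 + np.sum(stats_sim >= stat_obs - 1e-12)) / (mc_replications + 1.0))


def group_profile_table(
    groups: ConcordanceGroups,
    covariates: pd.DataFrame,
    sh_class_draws: dict | None = None,
    continuous: tuple = ("baseline_age",),
    categorical: tuple = ("female", "education"),
    mc_replications: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Descriptive profile of the four concordance groups with pooled tests.

    Descriptives (mean/SD for continuous variables, counts and column
    percentages for categorical ones, including social-health class
    assignments) are computed on the modal grouping, as is conventional
    for presentation.  The p-values are computed per pseudo-class
    imputation — one-way ANOVA for continuous variables, chi-square for
    categorical ones, with a Monte Carlo reference distribution
    (``mc_replications`` tables) when an expected cell count drops below
    five — and combined across imputations on the probit scale by Rubin's
    rules.  Groups with fewer than two modal members are described but
    excluded from testing, with a note.
    """
    rng = np.random.default_rng(seed)
    m = groups.draws.shape[0]
    modal = groups.modal
    rows = []

    group_sizes = {lab: int(np.sum(modal == i)) for i, lab in enumerate(CONCORDANCE_LABELS)}
    testable = [i for i in range(len(CONCORDANCE_LABELS)) if np.sum(modal == i) >= 2]
    note_skip = "" if len(testable) == len(CONCORDANCE_LABELS) else "groups with <2 subjects excluded from test"

    def pooled_p_continuous(values):
        ps = []
        for j in range(m):
            g = groups.draws[j]
            samples = [values[(g == i) & ~np.isnan(values)] for i in np.unique(g)]
            samples = [s for s in samples if s.size >= 2]
            if len(samples) < 2:
                ps.append(np.nan)
                continue
            ps.append(stats.f_oneway(*samples)[1])
        ps = [p for p in ps if np.isfinite(p)]
        return pool_pvalues(ps) if ps else np.nan

    def pooled_p_categorical(codes, n_levels):
        ps = []
        for j in range(m):
            g = groups.draws[j]
            tab = np.zeros((len(CONCORDANCE_LABELS), n_levels))
            for gi in range(len(CONCORDANCE_LABELS)):
                for lv in range(n_levels):
                    tab[gi, lv] = np.sum((g == gi) & (codes == lv))
            p = _chi2_pvalue(tab, rng, mc_replications)
            if np.isfinite(p):
                ps.append(p)
        return pool_pvalues(ps) if ps else np.nan

    for var in continuous:
        values = covariates[var].to_numpy(dtype=float)
        row = {"variable": var, "type": "continuous"}
        for i, lab in enumerate(CONCORDANCE_LABELS):
            sel = values[(modal == i) & ~np.isnan(values)]
            row[f"{lab} (n={group_sizes[lab]})"] = (
                f"{sel.mean():.1f} ({sel.std(ddof=1):.1f})" if sel.size >= 2 else "—"
            )
        row["p_pooled"] = pooled_p_continuous(values)
        row["note"] = note_skip
        rows.append(row)

    def add_categorical(var, codes, level_names):
        n_levels = len(level_names)
        for lv, lname in enumerate(level_names):
            row = {"variable": f"{var} = {lname}", "type": "categorical"}
            for i, lab in enumerate(CONCORDANCE_LABELS):
                sel = codes[modal == i]
                cnt = int(np.sum(sel == lv))
                pct = 100.0 * cnt / sel.size if sel.size else np.nan
                row[f"{lab} (n={group_sizes[lab]})"] = f"{cnt} ({pct:.0f}%)"
            row["p_pooled"] = pooled_p_categorical(codes, n_levels) if lv == 0 else np.nan
            row["note"] = note_skip
            rows.append(row)

    for var in categorical:
        col = covariates[var]
        if col.dtype.kind in "ifb":
            codes = col.to_numpy(dtype=float).astype(int)
            level_names = [str(v) for v in sorted(np.unique(codes))]
            codes = np.searchsorted(np.sort(np.unique(codes)), codes)
        else:
            cat = pd.Categorical(col.astype(str))
            codes = cat.codes.astype(int)
            level_names = list(cat.categories)
        add_categorical(var, codes, level_names)

    if sh_class_draws:
        for domain, (draws, modal_cls) in sh_class_draws.items():
            draws = np.atleast_2d(draws)
            codes = np.asarray(modal_cls, dtype=int) - 1
            n_levels = int(draws.max())
            level_names = [f"class {k}" for k in range(1, n_levels + 1)]
            # pooled test cross-tabulates the j-th draw of group and class
            ps = []
            for j in range(min(m, draws.shape[0])):
                g = groups.draws[j]
                d = draws[j] - 1
                tab = np.zeros((len(CONCORDANCE_LABELS), n_levels))
                for gi in range(len(CONCORDANCE_LABELS)):
                    for lv in range(n_levels):
                        tab[gi, lv] = np.sum((g == gi) & (d == lv))
                p = _chi2_pvalue(tab, rng, mc_replications)
                if np.isfinite(p):
                    ps.append(p)
            for lv, lname in enumerate(level_names):
                row = {"variable": f"{domain} {lname}", "type": "categorical"}
                for i, lab in enumerate(CONCORDANCE_LABELS):
                    sel = codes[modal == i]
                    cnt = int(np.sum(sel == lv))
                    pct = 100.0 * cnt / sel.size if sel.size else np.nan
                    row[f"{lab} (n={group_sizes[lab]})"] = f"{cnt} ({pct:.0f}%)"
                row["p_pooled"] = (pool_pvalues(ps) if ps else np.nan) if lv == 0 else np.nan
                row["note"] = note_skip
                rows.append(row)

    return pd.DataFrame(rows)
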