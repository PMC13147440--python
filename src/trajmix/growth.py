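"""Likelihood and EM machinery for latent trajectory mixture models.

One model family covers all three analysis stages:

* LGCA — a single-class latent growth curve (mixed-effects polynomial);
* LCGA — a mixture of polynomial trajectories with no, or only a shared,
  random intercept;
* GMM — a mixture permitting within-class random intercepts and slopes,
  either shared across classes or class-specific.

The mean of class ``k`` for a subject with centred baseline age ``a`` is

    m(t) = (b0k + g0k*a) + (b1k + g1k*a)*t + (b2k + g2k*a)*t**2

i.e. every growth parameter interacts with baseline age when
``age_interactions`` is on.  Estimation maximizes the observed-entries
marginal likelihood (the full-information ML analogue under missing at
random): subjects contribute only the waves at which the outcome was
recorded.  The EM treats both class labels and random effects as missing
data, so all conditional-maximization updates are closed form and the
observed-data log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajmix.cohort import AGE_CENTER

__all__ = [
    "GrowthSpec",
    "MixtureParams",
    "FitResult",
    "CohortDesign",
    "class_conditional_marginal",
    "loglik",
    "e_step",
    "m_step",
    "fit_em",
    "random_start_fit",
    "fit_growth_model",
    "simulate_design",
]

_RE_DIM = {"none": 0, "intercept": 1, "intercept_slope": 2}

DEFAULT_TIME_POINTS = (0.0, 3.0, 6.0, 9.0, 12.0)


class NumericalError(RuntimeError):
    """Raised when a likelihood evaluation degenerates (zero density, singular V)."""


@dataclass(frozen=True)
class GrowthSpec:
    """Declarative description of one candidate trajectory model."""

    degree: int = 2
    age_interactions: bool = True
    n_classes: int = 1
    random_effects: str = "intercept"  # none | intercept | intercept_slope
    random_effects_scope: str = "shared"  # shared | class_specific
    resid_variance: str = "shared"  # shared | free (per wave)
    time_points: tuple = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.random_effects not in _RE_DIM:
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.random_effects_scope not in ("shared", "class_specific"):
            raise ValueError("random_effects_scope must be 'shared' or 'class_specific'")
        if self.resid_variance not in ("shared", "free"):
            raise ValueError("resid_variance must be 'shared' or 'free'")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def n_re(self) -> int:
        return _RE_DIM[self.random_effects]

    @property
    def n_fixed(self) -> int:
        base = self.degree + 1
        return base * 2 if self.age_interactions else base

    @property
    def n_parameters(self) -> int:
        """Free-parameter count (for information criteria)."""
        k = self.n_classes
        q = self.n_re
        n_psi = q * (q + 1) // 2
        if q and self.random_effects_scope == "class_specific":
            n_psi *= k
        n_sig = len(self.time_points) if self.resid_variance == "free" else 1
        return k * self.n_fixed + n_psi + n_sig + (k - 1)

    def variant_label(self) -> str:
        return (
            f"K{self.n_classes}-deg{self.degree}-re_{self.random_effects}"
            f"-{self.random_effects_scope}-sig_{self.resid_variance}"
        )


@dataclass
class MixtureParams:
    """All estimated quantities of one fitted (or generating) model.

    ``beta`` is (K, p) with columns ordered as the powers of time followed,
    when age interactions are on, by the age-by-power products.  ``psi`` is
    (K, q, q); under shared scope all K blocks are identical.  ``sigma2``
    holds one residual variance per nominal wave (all equal under the
    shared constraint).
    """

    pi: np.ndarray
    beta: np.ndarray
    psi: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float)
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "psi": self.psi.tolist(),
            "sigma2": self.sigma2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(
            pi=np.array(d["pi"]),
            beta=np.array(d["beta"]),
            psi=np.array(d["psi"]),
            sigma2=np.array(d["sigma2"]),
        )


@dataclass
class FitResult:
    """Outcome of one EM fit."""

    spec: GrowthSpec
    params: MixtureParams
    loglik: float
    n_parameters: int
    converged: bool
    n_iterations: int
    posteriors: np.ndarray
    n_subjects: int
    degenerate: bool = False
    start_id: int | None = None
    n_best_replicates: int | None = None
    loglik_trace: list = field(default_factory=list)
    subject_ids: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_parameters": self.n_parameters,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_iterations": self.n_iterations,
            "n_subjects": self.n_subjects,
            "start_id": self.start_id,
            "n_best_replicates": self.n_best_replicates,
        }


# ---------------------------------------------------------------------------
# design: pattern-grouped view of a long cohort table


class CohortDesign:
    """Pattern-grouped view of one outcome in a long-format cohort.

    Subjects are grouped by their set of observed waves so that, within a
    group, all marginal covariance matrices coincide per class and can be
    factorized once per EM iteration.
    """

    def __init__(self, subject_ids, ages_centered, wave_idx_groups, y_groups, idx_groups, spec_times):
        self.subject_ids = np.asarray(subject_ids)
        self.ages = np.asarray(ages_centered, dtype=float)
        self.groups = []
        self.time_points = np.asarray(spec_times, dtype=float)
        for widx, y, idx in zip(wave_idx_groups, y_groups, idx_groups):
            widx = np.asarray(widx, dtype=int)
            self.groups.append(
                {
                    "wave_idx": widx,
                    "times": self.time_points[widx],
                    "y": np.asarray(y, dtype=float),
                    "idx": np.asarray(idx, dtype=int),
                }
            )
        self.n_subjects = len(self.subject_ids)
        self.n_obs = sum(g["y"].size for g in self.groups)

    @classmethod
    def from_frame(
        cls,
        cohort: pd.DataFrame,
        outcome: str,
        time_points=DEFAULT_TIME_POINTS,
        id_col: str = "id",
        time_col: str = "wave_time_years",
        age_col: str = "baseline_age",
    ) -> "CohortDesign":
        tp = np.asarray(time_points, dtype=float)
        df = cohort[[id_col, time_col, age_col, outcome]].dropna(subset=[outcome])
        if df.empty:
            raise ValueError(f"no observed values for outcome {outcome!r}")
        t = df[time_col].to_numpy(dtype=float)
        widx = np.abs(t[:, None] - tp[None, :]).argmin(axis=1)
        if not np.allclose(t, tp[widx], atol=0.51):
            bad = np.argmax(~np.isclose(t, tp[widx], atol=0.51))
            raise ValueError(f"wave time {t[bad]} does not match any nominal time point")
        df = df.assign(_widx=widx)
        ids, ages, wave_groups, y_groups, idx_groups = [], [], {}, {}, {}
        grouped = df.groupby(id_col, sort=True)
        for i, (sid, sub) in enumerate(grouped):
            ids.append(sid)
            ages.append(sub[age_col].iloc[0] - AGE_CENTER)
            key = tuple(sorted(sub["_widx"].tolist()))
            sub = sub.sort_values("_widx")
            wave_groups.setdefault(key, [])
            y_groups.setdefault(key, [])
            idx_groups.setdefault(key, [])
            y_groups[key].append(sub[outcome].to_numpy(dtype=float))
            idx_groups[key].append(i)
        keys = sorted(y_groups)
        return cls(
            subject_ids=np.asarray(ids),
            ages_centered=np.asarray(ages, dtype=float),
            wave_idx_groups=[np.asarray(k) for k in keys],
            y_groups=[np.vstack(y_groups[k]) for k in keys],
            idx_groups=[np.asarray(idx_groups[k]) for k in keys],
            spec_times=tp,
        )

    @property
    def outcome_variance(self) -> float:
        if not hasattr(self, "_yvar"):
            allv = np.concatenate([g["y"].ravel() for g in self.groups])
            self._yvar = float(np.var(allv))
        return self._yvar


def _poly_basis(times: np.ndarray, degree: int) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.vstack([t**d for d in range(degree + 1)]).T  # (T, degree+1)


def _z_matrix(times: np.ndarray, n_re: int) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    cols = [np.ones_like(t), t][:n_re]
    return np.vstack(cols).T if n_re else np.zeros((t.size, 0))


def _mean_matrix(F: np.ndarray, ages: np.ndarray, beta_k: np.ndarray, spec: GrowthSpec):
    """Class-k mean profiles for all subjects in a pattern group: (n, T)."""
    p0 = spec.degree + 1
    base = F @ beta_k[:p0]
    if spec.age_interactions:
        return base[None, :] + np.outer(ages, F @ beta_k[p0:])
    return np.broadcast_to(base, (ages.size, F.shape[0]))


def class_conditional_marginal(subject_times, baseline_age, params: MixtureParams, k: int, spec: GrowthSpec):
    """Marginal mean vector and covariance of class ``k`` at the given waves.

    ``baseline_age`` is on the natural scale (years); the mean uses the
    centred age ``a = baseline_age - 60``.  Covariance is
    ``Z Psi_k Z' + diag(sigma2)`` with Z columns (1, t) as dictated by the
    random-effect structure.
    """
    t = np.asarray(subject_times, dtype=float)
    if t.size == 0:
        raise ValueError("at least one observed wave is required")
    a = float(baseline_age) - AGE_CENTER
    F = _poly_basis(t, spec.degree)
    m = _mean_matrix(F, np.array([a]), params.beta[k], spec)[0]
    q = spec.n_re
    tp = np.asarray(spec.time_points, dtype=float)
    widx = np.abs(t[:, None] - tp[None, :]).argmin(axis=1)
    V = np.diag(params.sigma2[widx].astype(float))
    if q:
        psi = params.psi[k]
        if np.min(np.linalg.eigvalsh(psi)) < -1e-8:
            raise ValueError("random-effect covariance must be positive semi-definite")
        Z = _z_matrix(t, q)
        V = Z @ psi @ Z.T + V
    return m, V


def _group_gaussians(design: CohortDesign, params: MixtureParams, spec: GrowthSpec):
    """Per-class log-density matrix (N, K) plus cached per-(group, class) factors."""
    N, K = design.n_subjects, params.n_classes
    logphi = np.empty((N, K))
    cache = []
    q = spec.n_re
    for g in design.groups:
        t = g["times"]
        F = _poly_basis(t, spec.degree)
        Z = _z_matrix(t, q)
        ages = design.ages[g["idx"]]
        sig = params.sigma2[g["wave_idx"]]
        entry = {"F": F, "Z": Z, "classes": []}
        for k in range(K):
            V = np.diag(sig)
            if q:
                V = Z @ params.psi[k] @ Z.T + V
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
                raise NumericalError(f"singular marginal covariance (class {k + 1})") from exc
            m = _mean_matrix(F, ages, params.beta[k], spec)
            r = g["y"] - m
            sol = np.linalg.solve(L, r.T)  # (T, n)
            quad = np.sum(sol * sol, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            logphi[g["idx"], k] = -0.5 * (t.size * np.log(2 * np.pi) + logdet + quad)
            entry["classes"].append({"L": L, "resid": r, "V": V})
        cache.append(entry)
    return logphi, cache


def loglik(design: CohortDesign, params: MixtureParams, spec: GrowthSpec) -> float:
    """Total observed-entries marginal log-likelihood of the mixture."""
    logphi, _ = _group_gaussians(design, params, spec)
    return float(_mixture_loglik(logphi, params.pi)[0])


def _mixture_loglik(logphi: np.ndarray, pi: np.ndarray):
    a = logphi + np.log(pi)[None, :]
    amax = a.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(amax)):
        bad = int(np.argmax(~np.isfinite(amax.ravel())))
        raise NumericalError(f"zero mixture density for subject index {bad}")
    lse = amax.ravel() + np.log(np.exp(a - amax).sum(axis=1))
    return lse.sum(), np.exp(a - lse[:, None])


def e_step(design: CohortDesign, params: MixtureParams, spec: GrowthSpec):
    """Posterior class probabilities (log-domain) and the current log-likelihood."""
    logphi, _ = _group_gaussians(design, params, spec)
    ll, post = _mixture_loglik(logphi, params.pi)
    return post, float(ll)


def m_step(
    design: CohortDesign,
    posteriors: np.ndarray,
    params: MixtureParams,
    spec: GrowthSpec,
    pi_floor: float | None = None,
    cache=None,
) -> tuple[MixtureParams, bool]:
    """One conditional-maximization pass of the EM.

    Treats class labels and random effects jointly as missing data; the
    random-effect moments are evaluated at the incoming ``params`` and the
    fixed effects, residual variances and random-effect covariances are
    then updated in closed form (ECM), which never decreases the
    observed-data log-likelihood.  Returns the updated parameters and a
    degeneracy flag (a mixing proportion collapsing below the floor).
    """
    N, K = posteriors.shape
    q = spec.n_re
    p0 = spec.degree + 1
    p = spec.n_fixed
    W = len(spec.time_points)
    floor = 1.0 / (10.0 * N) if pi_floor is None else pi_floor

    class_weight = posteriors.sum(axis=0)
    pi_new = class_weight / N
    degenerate = bool(np.any(pi_new < floor))

    if cache is None:
        _, cache = _group_gaussians(design, params, spec)

    # conditional random-effect moments per (group, class), at incoming params
    bhat = []  # list over groups: (n_g, K, q)
    bcov = []  # list over groups: (K, q, q)
    for entry, g in zip(cache, design.groups):
        Z = entry["Z"]
        bh = np.zeros((g["y"].shape[0], K, q))
        bc = np.zeros((K, q, q))
        if q:
            for k in range(K):
                psi = params.psi[k]
                V = entry["classes"][k]["V"]
                G = np.linalg.solve(V, Z @ psi).T  # psi Z' V^-1, (q, T)
                bh[:, k, :] = entry["classes"][k]["resid"] @ G.T
                bc[k] = psi - G @ Z @ psi
        bhat.append(bh)
        bcov.append(bc)

    # --- fixed effects: weighted LS of (y - Z bhat) with old residual weights
    beta_new = np.empty((K, p))
    for k in range(K):
        A = np.zeros((p, p))
        c = np.zeros(p)
        for entry, g, bh in zip(cache, design.groups, bhat):
            F = entry["F"]
            Z = entry["Z"]
            wts = posteriors[g["idx"], k]
            sig = params.sigma2[g["wave_idx"]]
            Fw = F / sig[:, None]
            S = F.T @ Fw  # F' W F
            e = g["y"] - (bh[:, k, :] @ Z.T if q else 0.0)
            ages = design.ages[g["idx"]]
            s0 = wts.sum()
            ce0 = Fw.T @ (wts[:, None] * e).sum(axis=0)
            if spec.age_interactions:
                s1 = (wts * ages).sum()
                s2 = (wts * ages**2).sum()
                A += np.block([[s0 * S, s1 * S], [s1 * S, s2 * S]])
                ce1 = Fw.T @ ((wts * ages)[:, None] * e).sum(axis=0)
                c += np.concatenate([ce0, ce1])
            else:
                A += s0 * S
                c += ce0
        beta_new[k] = np.linalg.solve(A + 1e-10 * np.eye(p), c)

    # --- residual variances given new beta (expectations still at old params)
    num = np.zeros(W)
    den = np.zeros(W)
    for entry, g, bh, bc in zip(cache, design.groups, bhat, bcov):
        F, Z = entry["F"], entry["Z"]
        ages = design.ages[g["idx"]]
        for k in range(K):
            wts = posteriors[g["idx"], k]
            m = _mean_matrix(F, ages, beta_new[k], spec)
            e = g["y"] - m - (bh[:, k, :] @ Z.T if q else 0.0)
            trace_term = np.einsum("ti,ij,tj->t", Z, bc[k], Z) if q else 0.0
            contrib = (wts[:, None] * (e**2 + trace_term)).sum(axis=0)
            np.add.at(num, g["wave_idx"], contrib)
            np.add.at(den, g["wave_idx"], wts.sum())
    var_floor = 1e-6 * design.outcome_variance
    if spec.resid_variance == "shared":
        pooled = num.sum() / max(den.sum(), 1e-12)
        sigma2_new = np.full(W, max(pooled, var_floor))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            per = np.where(den > 0, num / np.maximum(den, 1e-12), params.sigma2)
        sigma2_new = np.maximum(per, var_floor)

    # --- random-effect covariances
    if q:
        psi_new = np.zeros((K, q, q))
        for k in range(K):
            S = np.zeros((q, q))
            wsum = 0.0
            for g, bh, bc in zip(design.groups, bhat, bcov):
                wts = posteriors[g["idx"], k]
                S += np.einsum("i,ij,ik->jk", wts, bh[:, k, :], bh[:, k, :]) + wts.sum() * bc[k]
                wsum += wts.sum()
            psi_new[k] = S / max(wsum, 1e-12)
        if spec.random_effects_scope == "shared":
            pooled = np.einsum("k,kij->ij", pi_new, psi_new)
            psi_new = np.broadcast_to(pooled, (K, q, q)).copy()
        # keep strictly PD for the next factorization
        for k in range(K):
            psi_new[k] = 0.5 * (psi_new[k] + psi_new[k].T)
            ev = np.linalg.eigvalsh(psi_new[k])
            if ev.min() < 1e-10 * max(ev.max(), 1.0):
                psi_new[k] += (1e-10 * max(ev.max(), 1.0) - min(ev.min(), 0.0)) * np.eye(q)
    else:
        psi_new = np.zeros((K, 0, 0))

    pi_safe = np.maximum(pi_new, 1e-12)
    pi_safe = pi_safe / pi_safe.sum()
    return MixtureParams(pi=pi_safe, beta=beta_new, psi=psi_new, sigma2=sigma2_new), degenerate


def canonical_order(params: MixtureParams) -> np.ndarray:
    """Class permutation sorting by model-implied outcome at t=0 for the
    reference age (descending), the package's label-switching convention."""
    return np.argsort(-params.beta[:, 0], kind="stable")


def _apply_order(params: MixtureParams, post: np.ndarray, order: np.ndarray):
    return (
        MixtureParams(
            pi=params.pi[order],
            beta=params.beta[order],
            psi=params.psi[order] if params.psi.size else params.psi,
            sigma2=params.sigma2,
        ),
        post[:, order],
    )


def fit_em(
    design: CohortDesign,
    spec: GrowthSpec,
    init: MixtureParams,
    tol: float = 1e-6,
    max_iter: int = 500,
    canonicalize: bool = True,
) -> FitResult:
    """Run EM to convergence from ``init``.

    Convergence is declared when the relative log-likelihood change drops
    below ``tol``; non-convergence within ``max_iter`` is flagged on the
    result rather than raised.  Classes are relabelled in canonical order
    (descending intercept at the reference age) on exit.
    """
    params = init
    trace = []
    logphi, cache = _group_gaussians(design, params, spec)
    ll, post = _mixture_loglik(logphi, params.pi)
    trace.append(ll)
    converged = False
    degenerate = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        params_new, degen = m_step(design, post, params, spec, cache=cache)
        degenerate = degenerate or degen
        logphi, cache = _group_gaussians(design, params_new, spec)
        ll_new, post = _mixture_loglik(logphi, params_new.pi)
        trace.append(ll_new)
        params = params_new
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        ll = ll_new
        if rel < tol:
            converged = True
            break
    if canonicalize and spec.n_classes > 1:
        order = canonical_order(params)
        params, post = _apply_order(params, post, order)
    return FitResult(
        spec=spec,
        params=params,
        loglik=float(ll),
        n_parameters=spec.n_parameters,
        converged=converged,
        n_iterations=n_iter,
        posteriors=post,
        n_subjects=design.n_subjects,
        degenerate=degenerate,
        loglik_trace=trace,
        subject_ids=design.subject_ids,
    )


# ---------------------------------------------------------------------------
# initialization and the multi-start strategy


def _subject_features(design: CohortDesign) -> np.ndarray:
    """Per-subject OLS (intercept, slope) features for k-means seeding."""
    cached = getattr(design, "_ols_features", None)
    if cached is not None:
        return cached
    feats = np.zeros((design.n_subjects, 2))
    for g in design.groups:
        t = g["times"]
        y = g["y"]
        if t.size >= 2:
            X = np.vstack([np.ones_like(t), t]).T
            coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
            feats[g["idx"], 0] = coef[0]
            feats[g["idx"], 1] = coef[1]
        else:
            feats[g["idx"], 0] = y[:, 0]
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = feats / sd
    design._ols_features = feats
    return feats


def params_from_responsibilities(
    design: CohortDesign, resp: np.ndarray, spec: GrowthSpec
) -> MixtureParams:
    """Moment-style starting values given soft class responsibilities."""
    N, K = resp.shape
    p0 = spec.degree + 1
    p = spec.n_fixed
    beta = np.zeros((K, p))
    resid = np.zeros(K)
    for k in range(K):
        A = np.zeros((p, p))
        c = np.zeros(p)
        sse = 0.0
        wobs = 0.0
        for g in design.groups:
            F = _poly_basis(g["times"], spec.degree)
            wts = resp[g["idx"], k]
            ages = design.ages[g["idx"]]
            S = F.T @ F
            if spec.age_interactions:
                s0, s1, s2 = wts.sum(), (wts * ages).sum(), (wts * ages**2).sum()
                A += np.block([[s0 * S, s1 * S], [s1 * S, s2 * S]])
                c += np.concatenate(
                    [
                        F.T @ (wts[:, None] * g["y"]).sum(axis=0),
                        F.T @ ((wts * ages)[:, None] * g["y"]).sum(axis=0),
                    ]
                )
            else:
                A += wts.sum() * S
                c += F.T @ (wts[:, None] * g["y"]).sum(axis=0)
        beta[k] = np.linalg.solve(A + 1e-8 * np.eye(p), c)
        for g in design.groups:
            F = _poly_basis(g["times"], spec.degree)
            wts = resp[g["idx"], k]
            m = _mean_matrix(F, design.ages[g["idx"]], beta[k], spec)
            sse += (wts[:, None] * (g["y"] - m) ** 2).sum()
            wobs += wts.sum() * g["times"].size
        resid[k] = sse / max(wobs, 1e-12)
    total_var = float(np.mean(resid))
    q = spec.n_re
    if q:
        tmax = max(float(np.max(spec.time_points)), 1.0)
        psi0 = np.diag([0.5 * total_var, 0.1 * total_var / tmax**2][:q])
        psi = np.broadcast_to(psi0, (K, q, q)).copy()
        sigma2 = np.full(len(spec.time_points), 0.5 * total_var)
    else:
        psi = np.zeros((K, 0, 0))
        sigma2 = np.full(len(spec.time_points), total_var)
    pi = np.maximum(resp.mean(axis=0), 1e-6)
    return MixtureParams(pi=pi / pi.sum(), beta=beta, psi=psi, sigma2=np.maximum(sigma2, 1e-8))


def _start_responsibilities(design: CohortDesign, K: int, rng: np.random.Generator, start: int):
    """Perturbed k-means-on-OLS-coefficients seeding for one random start."""
    feats = _subject_features(design)
    N = design.n_subjects
    if K == 1:
        return np.ones((N, 1))
    # lightweight k-means++ with a handful of Lloyd iterations
    centers = feats[rng.choice(N, size=K, replace=False)]
    for _ in range(10):
        d = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        for k in range(K):
            if np.any(lab == k):
                centers[k] = feats[lab == k].mean(axis=0)
    resp = np.full((N, K), 0.0)
    resp[np.arange(N), lab] = 1.0
    if start > 0:
        eps = rng.uniform(0.05, 0.5)
        resp = (1 - eps) * resp + eps * rng.dirichlet(np.ones(K), size=N)
    return resp / resp.sum(axis=1, keepdims=True)


def random_start_fit(
    design: CohortDesign,
    spec: GrowthSpec,
    n_starts: int = 500,
    n_init_iter: int = 20,
    n_final: int = 50,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Two-stage multi-start EM.

    ``n_starts`` randomized initializations (perturbed k-means on
    per-subject OLS growth coefficients) are run for ``n_init_iter`` EM
    iterations; the best ``n_final`` are continued to convergence and the
    highest-likelihood solution is returned.  ``n_best_replicates`` counts
    how many finalists reproduced the best log-likelihood (within 1e-3), a
    standard local-optimum diagnostic.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    short = []
    for s in range(n_starts):
        resp = _start_responsibilities(design, spec.n_classes, rng, s)
        init = params_from_responsibilities(design, resp, spec)
        try:
            fit = fit_em(design, spec, init, tol=tol, max_iter=n_init_iter, canonicalize=False)
        except NumericalError:
            continue
        fit.start_id = s
        short.append(fit)
    if not short:
        raise NumericalError("all random starts failed")
    short.sort(key=lambda f: f.loglik, reverse=True)
    finalists = []
    for fit in short[: max(1, min(n_final, len(short)))]:
        try:
            fin = fit_em(design, spec, fit.params, tol=tol, max_iter=max_iter)
        except NumericalError:
            continue
        fin.start_id = fit.start_id
        finalists.append(fin)
    if not finalists:
        raise NumericalError("all finalist refinements failed")
    best = max(finalists, key=lambda f: f.loglik)
    best.n_best_replicates = sum(1 for f in finalists if f.loglik >= best.loglik - 1e-3)
    return best


def fit_growth_model(
    cohort: pd.DataFrame,
    outcome: str,
    spec: GrowthSpec,
    n_starts: int = 50,
    n_init_iter: int = 10,
    n_final: int = 5,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit one trajectory model to a long-format cohort table.

    Convenience wrapper: builds the pattern-grouped design for ``outcome``
    and runs the two-stage multi-start EM.
    """
    design = CohortDesign.from_frame(cohort, outcome, time_points=spec.time_points)
    return random_start_fit(
        design,
        spec,
        n_starts=n_starts,
        n_init_iter=n_init_iter,
        n_final=n_final,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
    )


# ---------------------------------------------------------------------------
# parametric simulation from a fitted model (bootstrap machinery)


def simulate_design(
    design: CohortDesign, params: MixtureParams, spec: GrowthSpec, rng: np.random.Generator
) -> CohortDesign:
    """Simulate a new outcome vector from ``params`` on the observed design.

    Keeps every subject's age and missingness pattern fixed (the standard
    parametric-bootstrap convention) and redraws class labels, random
    effects and residuals.
    """
    K = params.n_classes
    q = spec.n_re
    new_groups_y = []
    for g in design.groups:
        t = g["times"]
        n_g = g["y"].shape[0]
        F = _poly_basis(t, spec.degree)
        Z = _z_matrix(t, q)
        ages = design.ages[g["idx"]]
        lab = rng.choice(K, size=n_g, p=params.pi)
        y = np.empty((n_g, t.size))
        for k in range(K):
            pick = lab == k
            if not pick.any():
                continue
            m = _mean_matrix(F, ages[pick], params.beta[k], spec)
            y_k = m + rng.standard_normal(m.shape) * np.sqrt(params.sigma2[g["wave_idx"]])
            if q:
                b = rng.multivariate_normal(np.zeros(q), params.psi[k], size=pick.sum())
                y_k = y_k + b @ Z.T
            y[pick] = y_k
        new_groups_y.append(y)
    return CohortDesign(
        subject_ids=design.subject_ids,
        ages_centered=design.ages,
        wave_idx_groups=[g["wave_idx"] for g in design.groups],
        y_groups=new_groups_y,
        idx_groups=[g["idx"] for g in design.groups],
        spec_times=design.time_points,
    )
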