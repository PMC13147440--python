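"""Model-fit diagnostics, class enumeration testing and the selection protocol.

Candidate trajectory models are compared on AIC/BIC (BIC penalizes with
the number of subjects), relative entropy of the posterior classification,
modal class sizes and average posterior probabilities, plus a parametric
bootstrap likelihood-ratio test for K versus K−1 classes.  The
:func:`run_three_phase_protocol` driver reproduces the stepwise search
used in trajectory-class studies: a single-class growth-curve grid first,
then latent-class growth models over two to four classes, then growth
mixture variants with progressively richer random-effect structures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trajmix.growth import (
    CohortDesign,
    FitResult,
    GrowthSpec,
    NumericalError,
    random_start_fit,
    simulate_design,
)

__all__ = [
    "information_criteria",
    "entropy",
    "class_diagnostics",
    "bootstrap_lrt",
    "BootstrapLRTResult",
    "ProtocolConfig",
    "SelectionReport",
    "run_three_phase_protocol",
]


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """AIC and BIC of a fitted model; BIC uses N = number of subjects."""
    q = fit.n_parameters
    aic = -2.0 * fit.loglik + 2.0 * q
    bic = -2.0 * fit.loglik + q * np.log(fit.n_subjects)
    return float(aic), float(bic)


def entropy(posteriors: np.ndarray) -> float:
    """Relative entropy of a posterior classification.

    ``E = 1 - sum_i sum_k (-p_ik ln p_ik) / (N ln K)`` with ``0 ln 0 := 0``;
    1 means perfectly separated classes, 0 a completely uninformative
    classification.  Undefined for a single class.
    """
    post = np.asarray(posteriors, dtype=float)
    n, k = post.shape
    if k < 2:
        raise ValueError("entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(k)))


@dataclass
class ClassDiagnostics:
    sizes: np.ndarray  # modal counts per class
    avepp: np.ndarray  # average posterior probability per modal class
    n_ties: int
    modal: np.ndarray  # modal assignment (0-based)


def class_diagnostics(posteriors: np.ndarray) -> ClassDiagnostics:
    """Modal class sizes and average posterior probability per modal class.

    Ties go to the lowest canonical class index and are counted.
    """
    post = np.asarray(posteriors, dtype=float)
    modal = post.argmax(axis=1)  # argmax takes the first maximum: the tie rule
    rowmax = post.max(axis=1)
    n_ties = int(((post == rowmax[:, None]).sum(axis=1) > 1).sum())
    k = post.shape[1]
    sizes = np.bincount(modal, minlength=k)
    avepp = np.array(
        [post[modal == j, j].mean() if sizes[j] else np.nan for j in range(k)]
    )
    return ClassDiagnostics(sizes=sizes, avepp=avepp, n_ties=n_ties, modal=modal)


@dataclass
class BootstrapLRTResult:
    lr_observed: float
    p_value: float
    n_boot: int
    n_used: int
    n_discarded: int
    null_lrs: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def reliable(self) -> bool:
        return self.n_discarded <= 0.2 * self.n_boot


def bootstrap_lrt(
    fit_k: FitResult,
    fit_km1: FitResult,
    design: CohortDesign,
    n_boot: int = 99,
    seed: int | None = None,
    n_starts: int = 2,
    n_init_iter: int = 10,
    n_final: int = 1,
    max_iter: int = 200,
) -> BootstrapLRTResult:
    """Parametric bootstrap likelihood-ratio test for K versus K−1 classes.

    Simulates ``n_boot`` datasets from the K−1 fit on the observed design,
    refits both models with reduced random starts, and returns
    ``p = (1 + #{LR* >= LR}) / (n_used + 1)``.  Draws whose refits fail
    are discarded and counted; the result is flagged unreliable when more
    than 20% are lost.
    """
    if fit_k.spec.n_classes != fit_km1.spec.n_classes + 1:
        raise ValueError("fits must differ by exactly one class")
    if n_boot < 19:
        raise ValueError("n_boot must be at least 19")
    lr_obs = 2.0 * (fit_k.loglik - fit_km1.loglik)
    rng = np.random.default_rng(seed)
    null_lrs = []
    n_discarded = 0
    for b in range(n_boot):
        sim = simulate_design(design, fit_km1.params, fit_km1.spec, rng)
        try:
            f0 = random_start_fit(
                sim, fit_km1.spec, n_starts=n_starts, n_init_iter=n_init_iter,
                n_final=n_final, seed=int(rng.integers(2**31 - 1)), max_iter=max_iter,
            )
            f1 = random_start_fit(
                sim, fit_k.spec, n_starts=n_starts, n_init_iter=n_init_iter,
                n_final=n_final, seed=int(rng.integers(2**31 - 1)), max_iter=max_iter,
            )
        except NumericalError:
            n_discarded += 1
            continue
        null_lrs.append(max(2.0 * (f1.loglik - f0.loglik), 0.0))
    null_lrs = np.asarray(null_lrs)
    n_used = null_lrs.size
    p = (1.0 + np.sum(null_lrs >= lr_obs)) / (n_used + 1.0)
    return BootstrapLRTResult(
        lr_observed=float(lr_obs),
        p_value=float(p),
        n_boot=n_boot,
        n_used=int(n_used),
        n_discarded=n_discarded,
        null_lrs=null_lrs,
    )


# ---------------------------------------------------------------------------
# the three-phase protocol


@dataclass
class ProtocolConfig:
    """Search grid and admissibility rules of the selection protocol."""

    k_range: tuple = (2, 3, 4)
    min_class_share: float = 0.01
    min_avepp: float = 0.70
    n_starts: int = 24
    n_init_iter: int = 8
    n_final: int = 3
    max_iter: int = 300
    lrt_n_boot: int = 0  # 0 disables the bootstrap LRT step
    seed: int = 0
    time_points: tuple = (0.0, 3.0, 6.0, 9.0, 12.0)
    age_interactions: bool = True


@dataclass
class CandidateRow:
    model_id: str
    phase: int
    spec: GrowthSpec
    fit: FitResult | None
    aic: float = np.nan
    bic: float = np.nan
    entropy: float = np.nan
    class_sizes: tuple = ()
    avepp: tuple = ()
    admissible: bool = False
    notes: str = ""


@dataclass
class SelectionReport:
    outcome: str
    candidates: list
    chosen_id: str | None
    trace: list
    lrt: BootstrapLRTResult | None = None

    @property
    def chosen(self) -> CandidateRow | None:
        for c in self.candidates:
            if c.model_id == self.chosen_id:
                return c
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "model_id": c.model_id,
                    "phase": c.phase,
                    "K": c.spec.n_classes,
                    "degree": c.spec.degree,
                    "random_effects": c.spec.random_effects,
                    "re_scope": c.spec.random_effects_scope,
                    "resid": c.spec.resid_variance,
                    "loglik": c.fit.loglik if c.fit else np.nan,
                    "n_params": c.spec.n_parameters,
                    "AIC": c.aic,
                    "BIC": c.bic,
                    "entropy": c.entropy,
                    "class_sizes": "/".join(str(s) for s in c.class_sizes),
                    "avepp": "/".join(f"{a:.3f}" for a in c.avepp),
                    "converged": bool(c.fit.converged) if c.fit else False,
                    "admissible": c.admissible,
                    "chosen": c.model_id == self.chosen_id,
                    "notes": c.notes,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "outcome": self.outcome,
            "chosen_id": self.chosen_id,
            "trace": self.trace,
            "candidates": json.loads(self.to_frame().to_json(orient="records")),
            "lrt": None
            if self.lrt is None
            else {
                "lr_observed": self.lrt.lr_observed,
                "p_value": self.lrt.p_value,
                "n_used": self.lrt.n_used,
                "n_discarded": self.lrt.n_discarded,
            },
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def _evaluate(row: CandidateRow, config: ProtocolConfig) -> CandidateRow:
    fit = row.fit
    if fit is None:
        row.admissible = False
        return row
    row.aic, row.bic = information_criteria(fit)
    diag = class_diagnostics(fit.posteriors)
    row.class_sizes = tuple(int(s) for s in diag.sizes)
    row.avepp = tuple(float(a) for a in diag.avepp)
    if fit.spec.n_classes > 1:
        row.entropy = entropy(fit.posteriors)
    reasons = []
    if not fit.converged:
        reasons.append("non-converged")
    if fit.degenerate:
        reasons.append("degenerate class")
    if fit.spec.n_classes > 1:
        if min(row.class_sizes) < config.min_class_share * fit.n_subjects:
            reasons.append(f"class below {config.min_class_share:.0%} floor")
        if np.nanmin(row.avepp) < config.min_avepp:
            reasons.append(f"AvePP below {config.min_avepp}")
    row.admissible = not reasons
    row.notes = "; ".join(reasons)
    return row


def _fit_candidate(design, spec, config, seed) -> FitResult | None:
    try:
        return random_start_fit(
            design,
            spec,
            n_starts=config.n_starts,
            n_init_iter=config.n_init_iter,
            n_final=config.n_final,
            seed=seed,
            max_iter=config.max_iter,
        )
    except NumericalError:
        return None


def run_three_phase_protocol(
    cohort: pd.DataFrame,
    outcome: str,
    config: ProtocolConfig | None = None,
) -> SelectionReport:
    """Stepwise class-enumeration protocol for one outcome.

    Phase 1 fits the one-class growth-curve grid (linear/quadratic time,
    intercept or intercept+slope random effects, shared or per-wave
    residual variances) and keeps the BIC-best structure.  Phase 2 fits
    latent-class growth models with two to four classes, with and without
    a shared random intercept; if no admissible phase-2 candidate improves
    on the phase-1 BIC the one-class solution is retained.  Phase 3 fits
    growth mixture variants (shared or class-specific random intercepts,
    optionally with random slopes) at the phase-2 class number.  The
    winner is the smallest-BIC converged, non-degenerate candidate; a
    bootstrap likelihood-ratio test of the winning K against K−1 is run
    when ``lrt_n_boot > 0``.  Every decision is recorded in ``trace``.
    """
    config = config or ProtocolConfig()
    rng = np.random.default_rng(config.seed)
    design = CohortDesign.from_frame(cohort, outcome, time_points=config.time_points)
    candidates: list[CandidateRow] = []
    trace: list[str] = []

    def add(phase, spec):
        fit = _fit_candidate(design, spec, config, int(rng.integers(2**31 - 1)))
        row = _evaluate(CandidateRow(model_id=f"p{phase}:{spec.variant_label()}", phase=phase, spec=spec, fit=fit), config)
        candidates.append(row)
        return row

    # Phase 1: one-class LGCA grid
    phase1 = []
    for degree in (1, 2):
        for re in ("intercept", "intercept_slope"):
            for resid in ("shared", "free"):
                spec = GrowthSpec(
                    degree=degree,
                    age_interactions=config.age_interactions,
                    n_classes=1,
                    random_effects=re,
                    random_effects_scope="shared",
                    resid_variance=resid,
                    time_points=config.time_points,
                )
                phase1.append(add(1, spec))
    ok1 = [r for r in phase1 if r.admissible]
    if not ok1:
        raise RuntimeError("all one-class growth models failed: " + "; ".join(r.notes for r in phase1))
    best1 = min(ok1, key=lambda r: r.bic)
    trace.append(f"phase1: best one-class model {best1.model_id} (BIC={best1.bic:.1f})")
    degree, resid = best1.spec.degree, best1.spec.resid_variance

    # Phase 2: LCGA, two to four classes, with and without random intercept
    phase2 = []
    for k in config.k_range:
        for re in ("none", "intercept"):
            spec = GrowthSpec(
                degree=degree,
                age_interactions=config.age_interactions,
                n_classes=k,
                random_effects=re,
                random_effects_scope="shared",
                resid_variance=resid,
                time_points=config.time_points,
            )
            phase2.append(add(2, spec))
    ok2 = [r for r in phase2 if r.admissible and r.bic < best1.bic]
    if not ok2:
        trace.append("phase2: no admissible multi-class model improves on one class; K=1 retained")
        chosen = best1
        report = SelectionReport(outcome=outcome, candidates=candidates, chosen_id=chosen.model_id, trace=trace)
        return report
    best2 = min(ok2, key=lambda r: r.bic)
    k_star = best2.spec.n_classes
    trace.append(f"phase2: best LCGA {best2.model_id} (K={k_star}, BIC={best2.bic:.1f})")

    # Phase 3: GMM variants (a)-(d) at the phase-2 class number
    phase3 = []
    for re, scope in (
        ("intercept", "shared"),
        ("intercept_slope", "shared"),
        ("intercept", "class_specific"),
        ("intercept_slope", "class_specific"),
    ):
        spec = GrowthSpec(
            degree=degree,
            age_interactions=config.age_interactions,
            n_classes=k_star,
            random_effects=re,
            random_effects_scope=scope,
            resid_variance=resid,
            time_points=config.time_points,
        )
        phase3.append(add(3, spec))

    pool = [r for r in candidates if r.admissible]
    chosen = min(pool, key=lambda r: r.bic)
    trace.append(f"winner: {chosen.model_id} (BIC={chosen.bic:.1f}) among {len(pool)} admissible candidates")

    lrt = None
    if config.lrt_n_boot and chosen.spec.n_classes > 1:
        spec_km1 = dataclasses.replace(chosen.spec, n_classes=chosen.spec.n_classes - 1)
        fit_km1 = _fit_candidate(design, spec_km1, config, int(rng.integers(2**31 - 1)))
        if fit_km1 is not None:
            lrt = bootstrap_lrt(
                chosen.fit,
                fit_km1,
                design,
                n_boot=config.lrt_n_boot,
                seed=int(rng.integers(2**31 - 1)),
                n_starts=2,
                n_init_iter=config.n_init_iter,
                max_iter=config.max_iter,
            )
            trace.append(
                f"bootstrap LRT K={chosen.spec.n_classes} vs {chosen.spec.n_classes - 1}: "
                f"LR={lrt.lr_observed:.2f}, p={lrt.p_value:.3f}"
            )
    return SelectionReport(outcome=outcome, candidates=candidates, chosen_id=chosen.model_id, trace=trace, lrt=lrt)
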