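"""Rubin's rules for combining estimates across multiple imputations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledEstimate", "pool_estimates", "pool_pvalues"]


@dataclass
class PooledEstimate:
    """A Rubin's-rule-combined scalar estimate.

    ``qbar`` is the mean of the per-imputation estimates, ``within`` the
    mean of their variances, ``between`` the sample variance of the
    estimates, and ``total = within + (1 + 1/m) * between``.  Degrees of
    freedom use the Barnard–Rubin small-sample adjustment when a
    complete-data df is supplied, otherwise the classical large-sample
    formula.  ``exponentiate`` marks log-scale estimates (odds ratios).
    """

    qbar: float
    within: float
    between: float
    total: float
    m: int
    df: float
    exponentiate: bool = False

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    @property
    def estimate(self) -> float:
        return float(np.exp(self.qbar)) if self.exponentiate else self.qbar

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df) if np.isfinite(self.df) else stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = self.qbar - tcrit * self.se, self.qbar + tcrit * self.se
        if self.exponentiate:
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 0.0 if self.qbar != 0 else 1.0
        t = self.qbar / self.se
        if np.isfinite(self.df):
            return float(2 * stats.t.sf(abs(t), self.df))
        return float(2 * stats.norm.sf(abs(t)))


def pool_estimates(
    estimates,
    variances,
    exponentiate: bool = False,
    df_com: float = np.inf,
) -> PooledEstimate:
    """Combine per-imputation point estimates and variances.

    When every draw yields the identical estimate the between-imputation
    variance is zero and the result reduces to the single-dataset
    estimate.  ``df_com`` is the complete-data degrees of freedom used by
    the Barnard–Rubin adjustment; infinite by default.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least two imputations")
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    r = (1.0 + 1.0 / m) * b / t if t > 0 else 0.0  # fraction of missing information
    if r < 1e-12:  # negligible missing information
        df = np.inf
    else:
        df_old = (m - 1) / r**2
        if np.isfinite(df_com):
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - r)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    return PooledEstimate(
        qbar=float(qbar), within=float(w), between=float(b), total=float(t),
        m=int(m), df=float(df), exponentiate=exponentiate,
    )


def pool_pvalues(p_values) -> float:
    """Combine per-imputation p-values on the probit scale.

    Each p is transformed to ``z = Phi^{-1}(1 - p)``, the z's are pooled
    by Rubin's rules with unit within-imputation variance, and the pooled
    ratio is referred to the t distribution (the Licht–Rubin method for
    significance tests under multiple imputation).
    """
    p = np.clip(np.asarray(p_values, dtype=float), 1e-15, 1 - 1e-15)
    z = stats.norm.isf(p)
    pooled = pool_estimates(z, np.ones_like(z))
    stat = pooled.qbar / pooled.se
    if np.isfinite(pooled.df):
        return float(stats.t.sf(stat, pooled.df))
    return float(stats.norm.sf(stat))
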