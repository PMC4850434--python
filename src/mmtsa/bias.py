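"""Small-study / publication-bias diagnostics.

Egger's regression test (ordinary least squares of the standardized
effect ``log_or/se`` on precision ``1/se``; a nonzero intercept indicates
funnel asymmetry), the Begg-Mazumdar rank-correlation test (Kendall's tau
between variance-standardized deviates and study variances, with the
continuity-corrected normal approximation), and funnel-plot coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate
from .meta import pool_fixed

__all__ = [
    "EggerResult",
    "BeggResult",
    "FunnelPoint",
    "egger_test",
    "begg_test",
    "funnel_coordinates",
    "plot_funnel",
]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p: float


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    log_or: float
    se: float


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Classical (unweighted) Egger regression for funnel asymmetry.

    Regresses z_i = log_or_i/se_i on precision 1/se_i by OLS with an
    intercept; the test statistic is intercept / SE(intercept) on k-2
    degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test needs at least 3 studies, got {k}")
    se = np.array([e.se for e in effects])
    y = np.array([e.log_or for e in effects]) / se
    x = 1.0 / se
    if np.ptp(x) < 1e-12:
        raise ValueError(
            "Egger regression undefined: all studies share one standard error "
            "(precision has no variance)"
        )
    X = np.column_stack([np.ones(k), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = k - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    intercept_se = math.sqrt(cov[0, 0])
    t = float(coef[0] / intercept_se)
    p = float(2 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=float(coef[0]),
        intercept_se=intercept_se,
        slope=float(coef[1]),
        t=t,
        df=df,
        p=p,
    )


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank correlation between effects and their variances.

    The deviates u_i = (theta_i - theta_fixed)/sqrt(v_i - v_pooled) are
    correlated (Kendall's tau-a) with the variances v_i; p comes from the
    continuity-corrected normal approximation of the concordance score.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Begg's test needs at least 3 studies, got {k}")
    lo = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    fixed = pool_fixed(list(effects))
    vstar = v - fixed.se**2
    vstar = np.maximum(vstar, 1e-12)  # guard: v_i can equal the pooled variance at k small
    u = (lo - fixed.log_or) / np.sqrt(vstar)
    # exhaustive pair count (tau-a), ties contribute zero
    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            s += int(np.sign(u[j] - u[i]) * np.sign(v[j] - v[i]))
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    z = max(abs(s) - 1, 0) / math.sqrt(var_s)
    p = float(2 * stats.norm.sf(z))
    return BeggResult(kendall_tau=tau, z=z, p=p)


def funnel_coordinates(
    effects: Sequence[EffectEstimate],
) -> tuple[list[FunnelPoint], float]:
    """(log OR, se) per study plus the pooled reference line value."""
    if len(effects) < 1:
        raise ValueError("funnel plot needs at least 1 study")
    points = [FunnelPoint(e.study_id, e.log_or, e.se) for e in effects]
    reference = pool_fixed(list(effects)).log_or
    return points, reference


def plot_funnel(effects: Sequence[EffectEstimate], path: Optional[str] = None, ax=None):
    """Scatter the funnel (log OR vs se, se axis inverted) with the pooled line."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points, ref = funnel_coordinates(effects)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter([p.log_or for p in points], [p.se for p in points], facecolors="none", edgecolors="C0")
    ax.axvline(ref, color="grey", ls="--", lw=1)
    ax.invert_yaxis()
    ax.set_xlabel("log OR")
    ax.set_ylabel("s.e. of log OR")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
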