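"""Pooling of study-level odds ratios with heterogeneity diagnostics.

The model organization follows the statsmodels convention: a
:class:`MetaAnalysis` object is built from a :class:`~mmtsa.study_data.StudySet`
(or loaded from CSV) for one genetic model; ``fit()`` returns a
:class:`PooledResult` carrying the pooled log odds ratio, its standard
error, the Wald confidence interval and the heterogeneity statistics, with
a ``summary()`` table.

Estimators
----------
fixed effect
    Mantel-Haenszel pooling of the 2x2 tables with the
    Robins-Breslow-Greenland variance (default for the fixed branch — it
    is what the standard meta-analysis software the field uses computes
    for count data), or classical inverse-variance weighting of Woolf log
    odds ratios (``pool_fixed``).
random effects
    DerSimonian-Laird: the between-study variance tau^2 is the moment
    estimator from Cochran's Q, and studies are weighted by
    1/(se_i^2 + tau^2).

Model choice follows the usual heterogeneity rule: random effects when
Q's p-value < 0.10 or I^2 > 50%, fixed effect otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .effects import ContrastTable, EffectEstimate, GeneticModel, build_contrast, study_effects
from .study_data import StudySet, load_studies

__all__ = [
    "HeterogeneityStats",
    "PooledResult",
    "heterogeneity",
    "pool_fixed",
    "pool_fixed_mh",
    "pool_random",
    "select_model",
    "leave_one_out",
    "MetaAnalysis",
    "table2",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, its p-value, Higgins' I^2 (%) and DerSimonian-Laird tau^2."""

    q: float
    df: int
    p_q: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled effect under one genetic model.

    Attributes mirror what a forest-plot row reports: the pooled OR with
    its 95% Wald CI and two-sided p, which pooling model produced it, the
    heterogeneity statistics of the study set, and the normalized
    per-study weights.
    """

    model_used: Literal["fixed", "random"]
    estimator: str
    genetic_model: Optional[GeneticModel]
    log_or: float
    se: float
    het: Optional[HeterogeneityStats]
    weights: tuple[float, ...]
    study_ids: tuple[str, ...] = ()
    alpha: float = 0.05

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        """95% confidence interval on the OR scale."""
        z = stats.norm.ppf(1 - self.alpha / 2)
        return (math.exp(self.log_or - z * self.se), math.exp(self.log_or + z * self.se))

    @property
    def z(self) -> float:
        return self.log_or / self.se

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z)))

    def summary(self) -> str:
        gm = self.genetic_model.contrast_label if self.genetic_model else "-"
        lo, hi = self.ci95
        lines = [
            "Pooled odds ratio",
            "=" * 46,
            f"genetic model    {gm}",
            f"pooling          {self.model_used} ({self.estimator})",
            f"studies          {self.k}",
            f"OR               {self.odds_ratio:.4f}",
            f"95% CI           ({lo:.4f}, {hi:.4f})",
            f"z / p            {self.z:.3f} / {self.p:.4f}",
        ]
        if self.het is not None:
            h = self.het
            lines += [
                f"Q (df, p)        {h.q:.3f} ({h.df}, {h.p_q:.4f})",
                f"I^2 / tau^2      {h.i2:.1f}% / {h.tau2:.5f}",
            ]
        return "\n".join(lines)


def _check_effects(effects: Sequence[EffectEstimate], k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise ValueError(f"{what} needs at least {k_min} studies, got {len(effects)}")


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q about the inverse-variance pooled mean, I^2 and DL tau^2."""
    _check_effects(effects, 2, "heterogeneity")
    lo = np.array([e.log_or for e in effects])
    w = np.array([e.weight_fixed for e in effects])
    theta_f = float((w * lo).sum() / w.sum())
    q = float((w * (lo - theta_f) ** 2).sum())
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def pool_fixed(
    effects: Sequence[EffectEstimate],
    genetic_model: Optional[GeneticModel] = None,
) -> PooledResult:
    """Inverse-variance fixed-effect pooling of Woolf log odds ratios."""
    _check_effects(effects, 1, "pool_fixed")
    lo = np.array([e.log_or for e in effects])
    w = np.array([e.weight_fixed for e in effects])
    theta = float((w * lo).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    het = heterogeneity(effects) if len(effects) >= 2 else None
    return PooledResult(
        model_used="fixed",
        estimator="inverse-variance",
        genetic_model=genetic_model,
        log_or=theta,
        se=se,
        het=het,
        weights=tuple(w / w.sum()),
        study_ids=tuple(e.study_id for e in effects),
    )


def pool_fixed_mh(
    tables: Sequence[ContrastTable],
    effects: Optional[Sequence[EffectEstimate]] = None,
    genetic_model: Optional[GeneticModel] = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR of 2x2 tables.

    The variance of the pooled log OR is Robins-Breslow-Greenland.  The
    heterogeneity block (and hence any reported I^2) still derives from
    the inverse-variance Q on the Woolf effects, which is what the
    standard software prints alongside an MH pool; pass ``effects`` to
    populate it.
    """
    if len(tables) < 1:
        raise ValueError("pool_fixed_mh needs at least 1 table")
    t = np.array([tb.as_tuple() for tb in tables], float)
    a, b, c, d = t.T
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    R, S = r.sum(), s.sum()
    if R <= 0 or S <= 0:
        raise ValueError("Mantel-Haenszel OR undefined: empty diagonal across all tables")
    log_or = float(np.log(R / S))
    p = (a + d) / n
    q = (b + c) / n
    var = float(
        (p * r).sum() / (2 * R**2)
        + (p * s + q * r).sum() / (2 * R * S)
        + (q * s).sum() / (2 * S**2)
    )
    het = heterogeneity(effects) if effects is not None and len(effects) >= 2 else None
    mh_w = s / S  # MH weights are proportional to b*c/n
    return PooledResult(
        model_used="fixed",
        estimator="mantel-haenszel",
        genetic_model=genetic_model,
        log_or=log_or,
        se=math.sqrt(var),
        het=het,
        weights=tuple(mh_w),
        study_ids=tuple(e.study_id for e in effects) if effects is not None else (),
    )


def pool_random(
    effects: Sequence[EffectEstimate],
    genetic_model: Optional[GeneticModel] = None,
    tau2: Optional[float] = None,
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    ``tau2`` overrides the moment estimate (useful for sensitivity
    analyses; 0 collapses to the fixed-effect result).
    """
    _check_effects(effects, 2, "pool_random")
    het = heterogeneity(effects)
    t2 = het.tau2 if tau2 is None else float(tau2)
    if t2 < 0:
        raise ValueError("tau2 must be non-negative")
    lo = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / (v + t2)
    theta = float((w * lo).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return PooledResult(
        model_used="random",
        estimator="dersimonian-laird",
        genetic_model=genetic_model,
        log_or=theta,
        se=se,
        het=het,
        weights=tuple(w / w.sum()),
        study_ids=tuple(e.study_id for e in effects),
    )


def select_model(het: HeterogeneityStats) -> Literal["fixed", "random"]:
    """Heterogeneity-driven model choice: random if p_Q < 0.10 or I^2 > 50%."""
    return "random" if (het.p_q < 0.10 or het.i2 > 50.0) else "fixed"


def leave_one_out(
    effects: Sequence[EffectEstimate],
    tables: Optional[Sequence[ContrastTable]] = None,
    genetic_model: Optional[GeneticModel] = None,
    fixed_estimator: str = "mantel-haenszel",
) -> list[PooledResult]:
    """Pool k times, omitting one study each time (model re-selected per subset)."""
    _check_effects(effects, 3, "leave_one_out")
    out = []
    for drop in range(len(effects)):
        sub = [e for i, e in enumerate(effects) if i != drop]
        het = heterogeneity(sub)
        if select_model(het) == "random":
            out.append(pool_random(sub, genetic_model))
        elif fixed_estimator == "mantel-haenszel" and tables is not None:
            sub_t = [t for i, t in enumerate(tables) if i != drop]
            out.append(pool_fixed_mh(sub_t, sub, genetic_model))
        else:
            out.append(pool_fixed(sub, genetic_model))
    return out


class MetaAnalysis:
    """Genetic-model meta-analysis of a set of case-control studies.

    Parameters
    ----------
    studies
        A :class:`~mmtsa.study_data.StudySet`.
    genetic_model
        Which genotype contrast to analyse (default: allele, T vs C).

    Examples
    --------
    >>> from mmtsa import MetaAnalysis, load_table1
    >>> res = MetaAnalysis(load_table1(), "allele").fit()
    >>> round(res.odds_ratio, 2)
    1.17
    """

    def __init__(self, studies: StudySet, genetic_model: Union[str, GeneticModel] = GeneticModel.ALLELE):
        self.studies = studies
        self.genetic_model = GeneticModel(genetic_model)
        self.effects = study_effects(studies, self.genetic_model)
        self.tables = [build_contrast(rec, self.genetic_model) for rec in studies]

    @classmethod
    def from_csv(cls, path: Union[str, Path], genetic_model: Union[str, GeneticModel] = GeneticModel.ALLELE) -> "MetaAnalysis":
        return cls(load_studies(path), genetic_model)

    def heterogeneity(self) -> HeterogeneityStats:
        return heterogeneity(self.effects)

    def fit(
        self,
        method: Literal["auto", "fixed", "random"] = "auto",
        fixed_estimator: Literal["mantel-haenszel", "inverse-variance"] = "mantel-haenszel",
    ) -> PooledResult:
        """Pool the studies; ``auto`` picks fixed/random from heterogeneity."""
        if method == "auto":
            if len(self.effects) == 1:
                method = "fixed"
            else:
                method = select_model(self.heterogeneity())
        if method == "random":
            return pool_random(self.effects, self.genetic_model)
        if fixed_estimator == "mantel-haenszel":
            return pool_fixed_mh(self.tables, self.effects, self.genetic_model)
        return pool_fixed(self.effects, self.genetic_model)

    def leave_one_out(self) -> list[PooledResult]:
        return leave_one_out(self.effects, self.tables, self.genetic_model)


def table2(studies: StudySet) -> pd.DataFrame:
    """Pooled results for all five genetic models, one row per model.

    Columns mirror a published summary table: contrast, OR, CI bounds,
    p, the selected pooling model, and I^2.
    """
    rows = []
    for gm in GeneticModel:
        res = MetaAnalysis(studies, gm).fit()
        lo, hi = res.ci95
        rows.append(
            {
                "genetic_model": gm.value,
                "contrast": gm.contrast_label,
                "or": res.odds_ratio,
                "ci_low": lo,
                "ci_high": hi,
                "p": res.p,
                "model": res.model_used,
                "i2": res.het.i2 if res.het else float("nan"),
                "tau2": res.het.tau2 if res.het else float("nan"),
                "q_p": res.het.p_q if res.het else float("nan"),
            }
        )
    return pd.DataFrame(rows)
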