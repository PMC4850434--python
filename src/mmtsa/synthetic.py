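"""Synthetic case-control study sets with known truth.

The generator emulates the structure the meta-analysis assumes: each
study draws a control minor-allele frequency ``q``, control genotypes
multinomial under Hardy-Weinberg proportions ``((1-q)^2, 2q(1-q), q^2)``,
and case genotypes from the exponentially tilted distribution

    P(case genotype g) ∝ HWE(g) * exp(theta_i * dose(g)),   dose = 0, 1, 2

— the generative counterpart of a logistic disease model with a
per-allele log odds ratio ``theta_i`` (so the allele-model OR of a large
study converges to ``exp(theta_i)``).  Between-study heterogeneity enters
through ``theta_i ~ Normal(theta, tau2)``.

Defaults mirror the bundled nine-study *MTHFR* C677T dataset: control T
frequencies span 0.20-0.50, theta = ln(1.17), tau2 = 0.0175 (the
DerSimonian-Laird estimate on that dataset), and study sizes span its
observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .study_data import GenotypeCounts, StudyRecord, StudySet

__all__ = ["SyntheticConfig", "generate_study", "generate_studyset", "StudySetTruth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a simulated study set."""

    n_studies: int = 9
    control_allele_freq_range: tuple[float, float] = (0.20, 0.50)
    theta: float = math.log(1.17)
    tau2: float = 0.0175
    n_cases_range: tuple[int, int] = (30, 1300)
    n_controls_range: tuple[int, int] = (80, 1800)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.control_allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("control_allele_freq_range must satisfy 0 < low <= high < 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        for name in ("n_cases_range", "n_controls_range"):
            a, b = getattr(self, name)
            if not (0 < a <= b):
                raise ValueError(f"{name} must be a non-empty positive range")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


@dataclass(frozen=True)
class StudySetTruth:
    """The parameters actually drawn for one simulated study set."""

    theta: float
    tau2: float
    study_thetas: tuple[float, ...]
    control_freqs: tuple[float, ...]


def _case_probs(q: float, theta: float) -> np.ndarray:
    """Genotype probabilities in cases: tilted HWE, dose = (0, 1, 2) T alleles."""
    p = 1.0 - q
    hwe = np.array([p * p, 2 * p * q, q * q])
    tilt = hwe * np.exp(theta * np.arange(3))
    return tilt / tilt.sum()


def generate_study(
    cfg: SyntheticConfig,
    study_theta: float,
    rng: np.random.Generator,
    study_id: str = "synthetic",
    year: int = 2000,
) -> StudyRecord:
    """Draw one case-control study with per-allele log OR ``study_theta``."""
    q = float(rng.uniform(*cfg.control_allele_freq_range))
    n_controls = int(rng.integers(cfg.n_controls_range[0], cfg.n_controls_range[1] + 1))
    n_cases = int(rng.integers(cfg.n_cases_range[0], cfg.n_cases_range[1] + 1))
    p = 1.0 - q
    ctrl = rng.multinomial(n_controls, [p * p, 2 * p * q, q * q])
    case = rng.multinomial(n_cases, _case_probs(q, study_theta))
    return StudyRecord(
        study_id=study_id,
        year=year,
        country="Simulated",
        ethnicity="Simulated",
        genotyping_method="simulation",
        control_source="simulation",
        cases=GenotypeCounts(*(int(c) for c in case)),
        controls=GenotypeCounts(*(int(c) for c in ctrl)),
    )


def generate_studyset(
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[StudySet, StudySetTruth]:
    """Draw a full study set plus the truth record behind it.

    With no explicit generator the config seed fixes the stream, so the
    same config always yields byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    thetas = rng.normal(cfg.theta, math.sqrt(cfg.tau2), size=cfg.n_studies)
    records, freqs = [], []
    for i, th in enumerate(thetas, start=1):
        rec = generate_study(cfg, float(th), rng, study_id=f"synthetic-{i:02d}", year=1999 + i)
        records.append(rec)
        freqs.append(rec.controls.t_frequency)
    truth = StudySetTruth(
        theta=cfg.theta,
        tau2=cfg.tau2,
        study_thetas=tuple(float(t) for t in thetas),
        control_freqs=tuple(freqs),
    )
    return StudySet(records), truth
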