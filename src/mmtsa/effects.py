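"""Hardy-Weinberg testing and per-study effect sizes under genetic models.

Each case-control study is reduced to a 2x2 contrast table under one of
five genetic models of a biallelic variant (here *MTHFR* C677T, minor
allele T):

==============  ==========================================
allele          T vs C (allele counts, 2 per subject)
homozygous      TT vs CC (heterozygotes excluded)
heterozygous    CT vs CC (TT excluded)
dominant        TT+CT vs CC
recessive       TT vs CT+CC
==============  ==========================================

The study-level effect is the log odds ratio with the Woolf (sum of
reciprocal cells) standard error; a 0.5 continuity correction is added to
all four cells only when a zero cell occurs.  Hardy-Weinberg equilibrium
in controls is checked with the 1-df Pearson chi-square (no Yates
correction) against expected counts from the sample allele frequency.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy import stats

from .study_data import GenotypeCounts, StudyRecord, StudySet

__all__ = [
    "GeneticModel",
    "ContrastTable",
    "HWEResult",
    "EffectEstimate",
    "hwe_test",
    "build_contrast",
    "study_effect",
    "study_effects",
]


class GeneticModel(str, enum.Enum):
    """The five genotype contrasts of a biallelic variant."""

    ALLELE = "allele"
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @property
    def contrast_label(self) -> str:
        return {
            GeneticModel.ALLELE: "T vs C",
            GeneticModel.HOMOZYGOUS: "TT vs CC",
            GeneticModel.HETEROZYGOUS: "CT vs CC",
            GeneticModel.DOMINANT: "TT+CT vs CC",
            GeneticModel.RECESSIVE: "TT vs CT+CC",
        }[self]


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 exposure-by-disease table under one genetic model.

    Counts are allele counts under the allele model and subject counts
    otherwise.  ``exposed`` carries the risk category (T allele, TT, ...).
    """

    exposed_cases: float
    unexposed_cases: float
    exposed_controls: float
    unexposed_controls: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.exposed_cases,
            self.unexposed_cases,
            self.exposed_controls,
            self.unexposed_controls,
        )

    @property
    def has_zero_cell(self) -> bool:
        return any(c == 0 for c in self.as_tuple())

    def corrected(self, increment: float = 0.5) -> "ContrastTable":
        """Add ``increment`` to every cell if any cell is zero."""
        if not self.has_zero_cell:
            return self
        a, b, c, d = self.as_tuple()
        return ContrastTable(a + increment, b + increment, c + increment, d + increment)

    def swapped(self) -> "ContrastTable":
        """Exchange exposed and unexposed columns (negates the log OR)."""
        a, b, c, d = self.as_tuple()
        return ContrastTable(b, a, d, c)


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions."""

    chi2: float
    p: float
    expected: tuple[float, float, float]


@dataclass(frozen=True)
class EffectEstimate:
    """A study-level log odds ratio with its Woolf standard error."""

    study_id: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.study_id!r}: standard error must be positive")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def weight_fixed(self) -> float:
        """Inverse-variance (fixed-effect) weight 1/se^2."""
        return 1.0 / self.variance

    @property
    def z(self) -> float:
        return self.log_or / self.se


def hwe_test(g: GenotypeCounts) -> HWEResult:
    """Chi-square test of Hardy-Weinberg equilibrium on one arm.

    Expected counts come from the sample allele frequency
    (p^2, 2pq, q^2) x n; the statistic is the 1-df Pearson chi-square
    without continuity correction.  A monomorphic sample fits HWE exactly
    and returns chi2 = 0, p = 1.
    """
    n = g.total
    if n <= 0:
        raise ValueError("HWE test needs at least one subject")
    q = g.t_frequency
    p = 1.0 - q
    expected = (p * p * n, 2.0 * p * q * n, q * q * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(chi2=0.0, p=1.0, expected=expected)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip(g.as_tuple(), expected) if exp > 0
    )
    return HWEResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), expected=expected)


def build_contrast(s: StudyRecord, m: GeneticModel) -> ContrastTable:
    """Collapse a study's genotype counts to the 2x2 table of model ``m``."""
    ca, co = s.cases, s.controls
    m = GeneticModel(m)
    if m is GeneticModel.ALLELE:
        return ContrastTable(ca.t_alleles, ca.c_alleles, co.t_alleles, co.c_alleles)
    if m is GeneticModel.HOMOZYGOUS:
        return ContrastTable(ca.tt, ca.cc, co.tt, co.cc)
    if m is GeneticModel.HETEROZYGOUS:
        return ContrastTable(ca.ct, ca.cc, co.ct, co.cc)
    if m is GeneticModel.DOMINANT:
        return ContrastTable(ca.tt + ca.ct, ca.cc, co.tt + co.ct, co.cc)
    return ContrastTable(ca.tt, ca.ct + ca.cc, co.tt, co.ct + co.cc)


def study_effect(t: ContrastTable, study_id: str = "") -> EffectEstimate:
    """Woolf log odds ratio of a 2x2 table.

    log OR = ln(ad/bc), se = sqrt(1/a + 1/b + 1/c + 1/d).  When any cell
    is zero, 0.5 is first added to all four cells; if a margin is still
    empty the effect is undefined.
    """
    a, b, c, d = t.corrected().as_tuple()
    if min(a, b, c, d) <= 0:
        raise ValueError(
            f"study {study_id!r}: odds ratio undefined (empty margin even after continuity correction)"
        )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(study_id=study_id, log_or=log_or, se=se)


def study_effects(s: StudySet, m: GeneticModel) -> list[EffectEstimate]:
    """Per-study effect estimates for every study in the set."""
    return [study_effect(build_contrast(rec, m), rec.study_id) for rec in s]
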