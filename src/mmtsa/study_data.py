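"""Per-study genotype-count tables for case-control meta-analysis.

A study contributes the counts of the three *MTHFR* C677T genotypes
(CC / CT / TT) among cases and among controls, plus descriptive metadata.
The packaged dataset bundles the nine multiple-myeloma case-control
studies (2,092 cases, 4,954 controls) that the downstream meta-analysis,
trial sequential analysis and Mendelian-randomization steps consume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "StudySet",
    "SchemaError",
    "ValidationError",
    "COLUMNS",
    "load_studies",
    "load_table1",
    "table1_path",
    "totals",
    "sort_chronological",
]

#: canonical column order of the delimited-text schema
COLUMNS = [
    "study_id",
    "year",
    "country",
    "ethnicity",
    "method",
    "control_source",
    "case_cc",
    "case_ct",
    "case_tt",
    "ctrl_cc",
    "ctrl_ct",
    "ctrl_tt",
]

_COUNT_COLUMNS = COLUMNS[6:]


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ValidationError(ValueError):
    """A study row carries an invalid (negative / non-integer) count."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm of a case-control study.

    ``cc`` counts major-allele homozygotes, ``ct`` heterozygotes and
    ``tt`` minor-allele homozygotes.
    """

    cc: int
    ct: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("cc", "ct", "tt"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"genotype count {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"genotype count {name!r} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.cc + self.ct + self.tt

    @property
    def t_alleles(self) -> int:
        """Number of minor (T) alleles carried by this arm."""
        return self.ct + 2 * self.tt

    @property
    def c_alleles(self) -> int:
        """Number of major (C) alleles carried by this arm."""
        return self.ct + 2 * self.cc

    @property
    def allele_total(self) -> int:
        return 2 * self.total

    @property
    def t_frequency(self) -> float:
        if self.total == 0:
            raise ValidationError("allele frequency undefined for an empty arm")
        return self.t_alleles / self.allele_total

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.cc, self.ct, self.tt)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: metadata plus genotype counts per arm."""

    study_id: str
    year: int
    country: str
    ethnicity: str
    genotyping_method: str
    control_source: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        if self.cases.total <= 0:
            raise ValidationError(f"study {self.study_id!r}: case arm is empty")
        if self.controls.total <= 0:
            raise ValidationError(f"study {self.study_id!r}: control arm is empty")

    @property
    def n_total(self) -> int:
        """Subjects contributed by this study (cases + controls)."""
        return self.cases.total + self.controls.total


class StudySet:
    """An ordered collection of :class:`StudyRecord` with unique ids.

    Order is preserved from the input; chronological re-ordering for the
    cumulative (trial-sequential) analysis is explicit via
    :meth:`sort_chronological`.
    """

    def __init__(self, studies: Iterable[StudyRecord]):
        studies = list(studies)
        if not studies:
            raise ValidationError("no studies: a StudySet needs at least one record")
        ids = [s.study_id for s in studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id(s): {dupes}")
        self._studies = studies

    @property
    def studies(self) -> list[StudyRecord]:
        return list(self._studies)

    def __len__(self) -> int:
        return len(self._studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self._studies)

    def __getitem__(self, i) -> StudyRecord:
        return self._studies[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, StudySet) and self._studies == other._studies

    def __repr__(self) -> str:
        nc, nk = self.totals()
        return f"<StudySet of {len(self)} studies: {nc} cases / {nk} controls>"

    def totals(self) -> tuple[int, int]:
        """Overall (n_cases, n_controls) across all studies."""
        return (
            sum(s.cases.total for s in self._studies),
            sum(s.controls.total for s in self._studies),
        )

    @property
    def n_subjects(self) -> int:
        nc, nk = self.totals()
        return nc + nk

    def sort_chronological(self) -> "StudySet":
        """Studies ordered by ascending year, ties broken by study_id."""
        return StudySet(sorted(self._studies, key=lambda s: (s.year, s.study_id)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self._studies:
            rows.append(
                {
                    "study_id": s.study_id,
                    "year": s.year,
                    "country": s.country,
                    "ethnicity": s.ethnicity,
                    "method": s.genotyping_method,
                    "control_source": s.control_source,
                    "case_cc": s.cases.cc,
                    "case_ct": s.cases.ct,
                    "case_tt": s.cases.tt,
                    "ctrl_cc": s.controls.cc,
                    "ctrl_ct": s.controls.ct,
                    "ctrl_tt": s.controls.tt,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StudySet":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise ValidationError("no studies: the table has a header but no data rows")
        records = []
        for _, row in df.iterrows():
            sid = str(row["study_id"])
            counts = {}
            for col in _COUNT_COLUMNS:
                raw = row[col]
                try:
                    val = float(raw)
                except (TypeError, ValueError):
                    raise ValidationError(f"study {sid!r}, column {col!r}: {raw!r} is not a number")
                if not float(val).is_integer():
                    raise ValidationError(f"study {sid!r}, column {col!r}: {raw!r} is not an integer count")
                if val < 0:
                    raise ValidationError(f"study {sid!r}, column {col!r}: negative count {raw!r}")
                counts[col] = int(val)
            try:
                year = int(row["year"])
            except (TypeError, ValueError):
                raise ValidationError(f"study {sid!r}: year {row['year']!r} is not an integer")
            records.append(
                StudyRecord(
                    study_id=sid,
                    year=year,
                    country=str(row["country"]),
                    ethnicity=str(row["ethnicity"]),
                    genotyping_method=str(row["method"]),
                    control_source=str(row["control_source"]),
                    cases=GenotypeCounts(counts["case_cc"], counts["case_ct"], counts["case_tt"]),
                    controls=GenotypeCounts(counts["ctrl_cc"], counts["ctrl_ct"], counts["ctrl_tt"]),
                )
            )
        return cls(records)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)


def load_studies(path: Union[str, Path, io.IOBase]) -> StudySet:
    """Read a delimited-text study table (comma or tab, autodetected).

    The header must name the columns in :data:`COLUMNS` (any order).
    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` for malformed counts or an empty table.
    """
    df = pd.read_csv(path, sep=None, engine="python", skip_blank_lines=True)
    return StudySet.from_dataframe(df)


def table1_path() -> Path:
    """Filesystem path of the packaged nine-study *MTHFR* C677T / MM table."""
    return Path(resources.files("mmtsa").joinpath("data/table1_mthfr_mm.csv"))  # type: ignore[arg-type]


def load_table1() -> StudySet:
    """Load the packaged nine-study dataset (2,092 cases / 4,954 controls)."""
    return load_studies(table1_path())


# -- free-function aliases mirroring the method API ------------------------

def totals(s: StudySet) -> tuple[int, int]:
    """Overall (n_cases, n_controls) of a study set."""
    return s.totals()


def sort_chronological(s: StudySet) -> StudySet:
    """Return the set ordered by ascending year (ties: study_id)."""
    return s.sort_chronological()
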