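"""Demography rosters, age/sex classification, and group-level covariates.

The demographic unit of the analysis is the group-year: a roster of
individuals resident in a group on a census date, summarized into the four
covariates used to predict cofeeding tolerance (fraction of infants under
three, fraction of females aged 5-12, group size, and fraction of
individuals with at least one co-resident maternal relative).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEXES = ("female", "male")

#: Left-closed, right-open age bins in whole years, and their labels.
DEFAULT_AGE_BINS: tuple[tuple[float, float, str], ...] = (
    (0, 3, "infant_lt3"),
    (3, 5, "young_3_4"),
    (5, 9, "juvenile_5_8"),
    (9, 13, "adolescent_9_12"),
    (13, float("inf"), "adult_13plus"),
)

AGE_CLASS_LABELS = tuple(label for _, _, label in DEFAULT_AGE_BINS)

DEMOGRAPHY_COLUMNS = (
    "id",
    "group",
    "sex",
    "birth_date",
    "mother_id",
    "entry_date",
    "exit_date",
)

#: Default census date (month, day) used to evaluate annual rosters.
DEFAULT_CENSUS_MONTH_DAY = (7, 1)

COVARIATE_NAMES = (
    "frac_infants_lt3",
    "frac_females_5_12",
    "group_size",
    "frac_maternal_kin",
)


class SchemaError(ValueError):
    """A required column is missing or malformed in an input file."""


class ValidationError(ValueError):
    """Input data violate a domain invariant."""


@dataclasses.dataclass(frozen=True)
class AgeSexClass:
    """Age-class x sex cell; age bins partition [0, inf)."""

    age_class: str
    sex: str

    @property
    def label(self) -> str:
        return f"{self.age_class}/{self.sex}"


@dataclasses.dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    birth_date: dt.date
    mother_id: str | None
    entry_date: dt.date
    exit_date: dt.date

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"individual {self.id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if self.exit_date < self.entry_date:
            raise ValidationError(
                f"individual {self.id!r}: exit_date {self.exit_date} precedes "
                f"entry_date {self.entry_date}"
            )

    def resident_on(self, date: dt.date) -> bool:
        return self.entry_date <= date <= self.exit_date


@dataclasses.dataclass(frozen=True)
class DemographyTable:
    """Roster of one group, evaluable at any query date."""

    group_id: str
    individuals: tuple[Individual, ...]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(
                f"group {self.group_id!r}: duplicate individual ids {dupes}"
            )
        roster_ids = set(ids)
        by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            if ind.mother_id is not None:
                if ind.mother_id not in roster_ids:
                    raise ValidationError(
                        f"group {self.group_id!r}: individual {ind.id!r} has "
                        f"mother_id {ind.mother_id!r} not on the roster"
                    )
                if by_id[ind.mother_id].sex != "female":
                    raise ValidationError(
                        f"group {self.group_id!r}: mother {ind.mother_id!r} of "
                        f"{ind.id!r} is not female"
                    )

    def __len__(self) -> int:
        return len(self.individuals)

    def roster_at(self, date: dt.date) -> tuple[Individual, ...]:
        return roster_at(self, date)


@dataclasses.dataclass(frozen=True)
class Demography:
    """All study groups' rosters, keyed by group id."""

    groups: Mapping[str, DemographyTable]

    def __getitem__(self, group_id: str) -> DemographyTable:
        return self.groups[group_id]

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for table in self.groups.values():
            for ind in table.individuals:
                rows.append(
                    {
                        "id": ind.id,
                        "group": table.group_id,
                        "sex": ind.sex,
                        "birth_date": ind.birth_date.isoformat(),
                        "mother_id": "" if ind.mother_id is None else ind.mother_id,
                        "entry_date": ind.entry_date.isoformat(),
                        "exit_date": ind.exit_date.isoformat(),
                    }
                )
        return pd.DataFrame(rows, columns=list(DEMOGRAPHY_COLUMNS))


def _parse_date(value: str, column: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise SchemaError(
            f"row {row}: column {column!r} is not an ISO-8601 date: {value!r}"
        ) from exc


def load_demography(path) -> Demography:
    """Read a demography CSV into validated per-group rosters.

    The file must contain the columns ``id, group, sex, birth_date,
    mother_id, entry_date, exit_date`` (ISO dates; empty ``mother_id``
    allowed). Unknown columns are ignored.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"demography file {path}: missing required column(s) {missing}")
    return demography_from_frame(frame)


def demography_from_frame(frame: pd.DataFrame) -> Demography:
    groups: dict[str, list[Individual]] = {}
    for row_idx, row in enumerate(frame.itertuples(index=False), start=2):
        mother = str(row.mother_id).strip()
        ind = Individual(
            id=str(row.id).strip(),
            sex=str(row.sex).strip(),
            birth_date=_parse_date(row.birth_date, "birth_date", row_idx),
            mother_id=mother or None,
            entry_date=_parse_date(row.entry_date, "entry_date", row_idx),
            exit_date=_parse_date(row.exit_date, "exit_date", row_idx),
        )
        groups.setdefault(str(row.group).strip(), []).append(ind)
    return Demography(
        groups={gid: DemographyTable(gid, tuple(inds)) for gid, inds in groups.items()}
    )


def write_demography(dem: Demography, path) -> None:
    dem.to_frame().to_csv(path, index=False)


def roster_at(table: DemographyTable, date: dt.date) -> tuple[Individual, ...]:
    """Individuals whose residency window contains ``date`` (closed interval)."""
    return tuple(ind for ind in table.individuals if ind.resident_on(date))


def age_in_years(ind: Individual, date: dt.date) -> int:
    """Age in completed whole years on ``date``."""
    if date < ind.birth_date:
        raise ValidationError(
            f"individual {ind.id!r}: query date {date} precedes birth date "
            f"{ind.birth_date}"
        )
    born = ind.birth_date
    return date.year - born.year - ((date.month, date.day) < (born.month, born.day))


def classify(
    ind: Individual,
    date: dt.date,
    age_bins: Sequence[tuple[float, float, str]] = DEFAULT_AGE_BINS,
) -> AgeSexClass:
    """Assign the age/sex class of ``ind`` on ``date``.

    Bins are left-closed and right-open in whole years, so an individual on
    its third birthday has already left the infant class.
    """
    age = age_in_years(ind, date)
    for lo, hi, label in age_bins:
        if lo <= age < hi:
            return AgeSexClass(label, ind.sex)
    raise ValidationError(f"age {age} not covered by the configured age bins")


def census_date(year: int, month_day: tuple[int, int] = DEFAULT_CENSUS_MONTH_DAY) -> dt.date:
    return dt.date(year, *month_day)


def has_dependent_infant(
    female: Individual, roster: Sequence[Individual], date: dt.date
) -> bool:
    """True if ``female`` has a co-resident offspring under three years old."""
    if female.sex != "female":
        return False
    for other in roster:
        if other.mother_id == female.id and age_in_years(other, date) < 3:
            return True
    return False


def _maternal_kin_present(ind: Individual, roster: Sequence[Individual]) -> bool:
    # Mother, maternal sibling (shared mother), or offspring on the roster.
    for other in roster:
        if other.id == ind.id:
            continue
        if ind.mother_id is not None and other.id == ind.mother_id:
            return True
        if (
            ind.mother_id is not None
            and other.mother_id is not None
            and other.mother_id == ind.mother_id
        ):
            return True
        if other.mother_id == ind.id:
            return True
    return False


def build_covariates(
    dem: Demography,
    years: Iterable[int],
    *,
    census_month_day: tuple[int, int] = DEFAULT_CENSUS_MONTH_DAY,
    age_bins: Sequence[tuple[float, float, str]] = DEFAULT_AGE_BINS,
    exclude_infants_from_denominator: bool = False,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per group-year demographic covariates, raw and globally z-scored.

    Fractions use the full census roster as denominator by default;
    ``exclude_infants_from_denominator`` removes infants under three from
    the denominator (they remain countable in the numerators that target
    them). Standardization is performed jointly over all group-year cells
    so that within- and between-group models share a covariate scale.
    """
    years = sorted(set(int(y) for y in years))
    rows = []
    for gid, table in dem.groups.items():
        for year in years:
            date = census_date(year, census_month_day)
            roster = roster_at(table, date)
            if not roster:
                raise ValidationError(f"group {gid!r}: empty roster in year {year}")
            n_total = len(roster)
            denom = n_total
            if exclude_infants_from_denominator:
                denom = sum(
                    1 for r in roster if classify(r, date, age_bins).age_class != "infant_lt3"
                )
                denom = max(denom, 1)
            n_infants = sum(
                1 for r in roster if classify(r, date, age_bins).age_class == "infant_lt3"
            )
            n_fem_5_12 = sum(
                1
                for r in roster
                if r.sex == "female" and 5 <= age_in_years(r, date) < 13
            )
            n_kin = sum(1 for r in roster if _maternal_kin_present(r, roster))
            rows.append(
                {
                    "group": gid,
                    "year": year,
                    "n_group": n_total,
                    "frac_infants_lt3": n_infants / denom,
                    "frac_females_5_12": n_fem_5_12 / denom,
                    "group_size": float(n_total),
                    "frac_maternal_kin": n_kin / denom,
                }
            )
    cov = pd.DataFrame(rows).sort_values(["group", "year"]).reset_index(drop=True)
    if standardize:
        for name in COVARIATE_NAMES:
            x = cov[name].to_numpy(dtype=float)
            sd = x.std()  # population SD: z-columns have SD exactly 1
            if sd == 0.0:
                warnings.warn(
                    f"covariate {name!r} is constant across all group-year cells; "
                    "its standardized column is set to zero",
                    stacklevel=2,
                )
                cov[name + "_z"] = 0.0
            else:
                cov[name + "_z"] = (x - x.mean()) / sd
    return cov


def covariate_matrix(cov: pd.DataFrame, names: Sequence[str] = COVARIATE_NAMES) -> np.ndarray:
    """Standardized design matrix aligned with the rows of ``cov``."""
    cols = [n + "_z" for n in names]
    missing = [c for c in cols if c not in cov.columns]
    if missing:
        raise SchemaError(f"covariate table lacks standardized column(s) {missing}")
    return cov[cols].to_numpy(dtype=float)
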