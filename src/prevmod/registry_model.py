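"""Domain types, CSV input/output and case-eligibility filtering.

The analysis operates on a minimal registry extract: one row per registered
first-primary case (with follow-up to the end of the observation window and
any subsequent metastasis / second-primary notifications), mid-year female
population counts by single year of age and calendar year, and an all-cause
life table of annual death probabilities on the same grid.

Conventions used throughout the package:

* time is discretised to integer calendar years; diagnoses occur at mid-year
  and durations run mid-year to mid-year,
* ages are attained-age integers; the analysed range is a closed interval
  (default 18-84); the 85+ open class may be carried in the population table
  but takes no part in any estimate,
* the study population is female only, so no sex field is carried.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VITAL_STATUSES = ("alive", "dead")
CAUSES = ("cancer", "other")
EVENT_TYPES = ("metastasis", "second_primary")

CASES_COLUMNS = [
    "case_id",
    "age_dx",
    "year_dx",
    "vital_status",
    "year_death",
    "cause_death",
    "dco_flag",
]
EVENTS_COLUMNS = ["case_id", "event_year", "event_type"]


class RegistryError(ValueError):
    """Raised for malformed registry inputs (bad schema or invalid rows)."""


@dataclass(frozen=True)
class CaseRecord:
    """One registered first-primary case with follow-up history.

    ``event_years`` lists subsequent notifications (metastasis or second
    primary) as ``(calendar_year, type)`` pairs; the registry cannot reliably
    separate the two, but both trigger further treatment, so downstream code
    mostly treats them together.
    """

    case_id: str
    age_dx: int
    year_dx: int
    vital_status: str
    year_death: int | None = None
    cause_death: str | None = None
    dco_flag: bool = False
    event_years: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.vital_status not in VITAL_STATUSES:
            raise RegistryError(
                f"case {self.case_id}: vital_status must be one of "
                f"{VITAL_STATUSES}, got {self.vital_status!r}"
            )
        if self.vital_status == "dead":
            if self.year_death is None:
                raise RegistryError(
                    f"case {self.case_id}: dead case without year_death"
                )
            if self.cause_death not in CAUSES:
                raise RegistryError(
                    f"case {self.case_id}: dead case needs cause_death in "
                    f"{CAUSES}, got {self.cause_death!r}"
                )
        elif self.year_death is not None:
            raise RegistryError(
                f"case {self.case_id}: alive case with year_death set"
            )
        if self.age_dx < 0:
            raise RegistryError(f"case {self.case_id}: negative age_dx")
        for year, etype in self.event_years:
            if etype not in EVENT_TYPES:
                raise RegistryError(
                    f"case {self.case_id}: unknown event type {etype!r}"
                )
            if year < self.year_dx:
                raise RegistryError(
                    f"case {self.case_id}: event year {year} precedes diagnosis"
                )

    @property
    def alive(self) -> bool:
        return self.vital_status == "alive"


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis settings with the study defaults.

    ``survival_periods`` must partition the observation years and
    ``survival_age_groups`` must partition ``[age_min, age_max]``.
    """

    age_min: int = 18
    age_max: int = 84
    obs_year_min: int = 1972
    obs_year_max: int = 2007
    proj_year_max: int = 2017
    survival_periods: tuple[tuple[int, int], ...] = (
        (1972, 1980),
        (1981, 1989),
        (1990, 1995),
        (1996, 2001),
        (2002, 2007),
    )
    survival_age_groups: tuple[tuple[int, int], ...] = (
        (18, 49),
        (50, 69),
        (70, 84),
    )
    long_term_cutoff_years: int = 10
    metastasis_lag_days: int = 120
    subphase_reference_year: int = 2006
    seed: int = 20140936

    def __post_init__(self) -> None:
        years = [y for lo, hi in self.survival_periods for y in range(lo, hi + 1)]
        if sorted(years) != list(range(self.obs_year_min, self.obs_year_max + 1)):
            raise ValueError("survival_periods must partition the observation years")
        ages = [a for lo, hi in self.survival_age_groups for a in range(lo, hi + 1)]
        if sorted(ages) != list(range(self.age_min, self.age_max + 1)):
            raise ValueError("survival_age_groups must partition [age_min, age_max]")
        if not (self.obs_year_min <= self.obs_year_max <= self.proj_year_max):
            raise ValueError("year bounds must satisfy obs_min <= obs_max <= proj_max")

    @property
    def max_duration(self) -> int:
        """Longest possible completed duration for a prevalent case aged <= age_max."""
        return self.age_max - self.age_min

    @property
    def backcast_year_min(self) -> int:
        """Earliest diagnosis year reachable by a prevalent case at obs_year_min."""
        return self.obs_year_min - self.max_duration

    def age_group_index(self, age_dx: int) -> int:
        for i, (lo, hi) in enumerate(self.survival_age_groups):
            if lo <= age_dx <= hi:
                return i
        raise ValueError(f"age {age_dx} outside configured age groups")

    def age_group_label(self, i: int) -> str:
        lo, hi = self.survival_age_groups[i]
        return f"{lo}-{hi}"

    def period_index(self, year_dx: int) -> int:
        for i, (lo, hi) in enumerate(self.survival_periods):
            if lo <= year_dx <= hi:
                return i
        raise ValueError(f"year {year_dx} outside configured periods")

    def period_midpoint(self, i: int) -> float:
        lo, hi = self.survival_periods[i]
        return 0.5 * (lo + hi)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


class _AgeYearGrid:
    """Rectangular (age x year) grid of nonnegative values with edge clamping.

    Lookups outside the year range freeze at the nearest observed year and
    lookups above the oldest tabulated age use the oldest age row; both are
    deliberate, documented extensions (stable-population backcast, and an
    open-ended top age class).
    """

    value_name = "value"

    def __init__(self, values: np.ndarray, ages: np.ndarray, years: np.ndarray):
        values = np.asarray(values, dtype=float)
        ages = np.asarray(ages, dtype=int)
        years = np.asarray(years, dtype=int)
        if values.shape != (ages.size, years.size):
            raise ValueError("grid shape does not match age/year axes")
        if not (np.all(np.diff(ages) == 1) and np.all(np.diff(years) == 1)):
            raise ValueError("age and year axes must be contiguous")
        if np.any(values < 0) or np.any(~np.isfinite(values)):
            raise ValueError(f"{self.value_name} must be finite and nonnegative")
        self.values = values
        self.ages = ages
        self.years = years

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    @property
    def year_min(self) -> int:
        return int(self.years[0])

    @property
    def year_max(self) -> int:
        return int(self.years[-1])

    def at(self, age, year):
        """Vectorised lookup with edge clamping on both axes."""
        ai = np.clip(np.asarray(age) - self.age_min, 0, self.ages.size - 1)
        yi = np.clip(np.asarray(year) - self.year_min, 0, self.years.size - 1)
        return self.values[ai, yi]

    def to_frame(self) -> pd.DataFrame:
        aa, yy = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame(
            {"age": aa.ravel(), "year": yy.ravel(), self.value_name: self.values.ravel()}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame):
        pivot = df.pivot(index="age", columns="year", values=cls.value_name)
        if pivot.isna().any().any():
            raise RegistryError(f"{cls.__name__}: grid is not rectangular")
        return cls(
            pivot.to_numpy(),
            pivot.index.to_numpy(),
            pivot.columns.to_numpy(),
        )


class PopulationTable(_AgeYearGrid):
    """Mid-year female population counts by single year of age and calendar year."""

    value_name = "count"

    def person_years(self, age, year):
        return self.at(age, year)

    def total(self, year: int, age_lo: int, age_hi: int) -> float:
        ages = np.arange(age_lo, age_hi + 1)
        return float(self.at(ages, np.full_like(ages, year)).sum())


class LifeTable(_AgeYearGrid):
    """Annual all-cause death probabilities qx by single year of age and year."""

    value_name = "qx"

    def __init__(self, values, ages, years):
        super().__init__(values, ages, years)
        if np.any(self.values > 1):
            raise ValueError("qx must lie in [0, 1]")

    def qx(self, age, year):
        return self.at(age, year)

    def expected_survival(self, age_dx, year_dx, d: int) -> float:
        """P(surviving d annual intervals) along the diagnosis-cohort diagonal.

        S_E = prod_{k=0}^{d-1} (1 - qx(age_dx + k, year_dx + k)); age and year
        advance together from the mid-year of diagnosis.  Edges are clamped.
        """
        if d < 0:
            raise ValueError("duration must be nonnegative")
        if d == 0:
            return 1.0
        k = np.arange(d)
        return float(np.prod(1.0 - self.qx(age_dx + k, year_dx + k)))


# ---------------------------------------------------------------------------
# CSV input/output


def _parse_int(value, what: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise RegistryError(f"row {row}: non-integer {what}: {value!r}") from None
    if not float(f).is_integer():
        raise RegistryError(f"row {row}: non-integer {what}: {value!r}")
    return int(f)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegistryError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_cases(path, config: AnalysisConfig, events_path=None) -> list[CaseRecord]:
    """Read case records from ``cases.csv`` (plus optional long-format events).

    Malformed rows raise :class:`RegistryError` with the offending row number
    (1-based, excluding the header).  An empty file with a valid header yields
    an empty list.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CASES_COLUMNS, path)

    events: dict[str, list[tuple[int, str]]] = {}
    if events_path is not None and Path(events_path).exists():
        ev = pd.read_csv(events_path, dtype=str, keep_default_na=False)
        _require_columns(ev, EVENTS_COLUMNS, events_path)
        for i, row in enumerate(ev.itertuples(index=False), start=1):
            year = _parse_int(row.event_year, "event_year", i)
            events.setdefault(row.case_id, []).append((year, row.event_type))

    cases: list[CaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            year_death = (
                None if row.year_death == "" else _parse_int(row.year_death, "year_death", i)
            )
            cause = None if row.cause_death == "" else row.cause_death
            cases.append(
                CaseRecord(
                    case_id=row.case_id,
                    age_dx=_parse_int(row.age_dx, "age_dx", i),
                    year_dx=_parse_int(row.year_dx, "year_dx", i),
                    vital_status=row.vital_status,
                    year_death=year_death,
                    cause_death=cause,
                    dco_flag=str(row.dco_flag).strip().lower() in ("1", "true", "t", "yes"),
                    event_years=tuple(sorted(events.get(row.case_id, ()))),
                )
            )
        except RegistryError as exc:
            raise RegistryError(f"{path}, row {i}: {exc}") from None
    return cases


def write_cases(cases: Iterable[CaseRecord], path, events_path=None) -> None:
    rows = []
    event_rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "age_dx": c.age_dx,
                "year_dx": c.year_dx,
                "vital_status": c.vital_status,
                "year_death": "" if c.year_death is None else c.year_death,
                "cause_death": "" if c.cause_death is None else c.cause_death,
                "dco_flag": str(c.dco_flag).lower(),
            }
        )
        for year, etype in c.event_years:
            event_rows.append({"case_id": c.case_id, "event_year": year, "event_type": etype})
    pd.DataFrame(rows, columns=CASES_COLUMNS).to_csv(path, index=False)
    if events_path is not None:
        pd.DataFrame(event_rows, columns=EVENTS_COLUMNS).to_csv(events_path, index=False)


def read_population(path) -> PopulationTable:
    df = pd.read_csv(path)
    _require_columns(df, ["age", "year", "count"], path)
    return PopulationTable.from_frame(df)


def write_population(table: PopulationTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_lifetable(path) -> LifeTable:
    df = pd.read_csv(path)
    _require_columns(df, ["age", "year", "qx"], path)
    return LifeTable.from_frame(df)


def write_lifetable(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Eligibility filter


def filter_eligible(
    cases: Sequence[CaseRecord], config: AnalysisConfig, tally: Counter | None = None
) -> list[CaseRecord]:
    """Apply the registry eligibility rules.

    A case is retained iff it was diagnosed within the closed age range and
    observation window and was not a death-certificate-only / post-mortem
    notification.  Exclusions are tallied by reason (pass ``tally`` to
    collect them); the filter is total and idempotent.
    """
    kept: list[CaseRecord] = []
    counts: Counter = Counter() if tally is None else tally
    for c in cases:
        if c.dco_flag:
            counts["DCO/post-mortem"] += 1
        elif not (config.age_min <= c.age_dx <= config.age_max):
            counts["age outside range"] += 1
        elif not (config.obs_year_min <= c.year_dx <= config.obs_year_max):
            counts["diagnosis outside window"] += 1
        else:
            kept.append(c)
    if counts:
        logger.info(
            "eligibility filter: kept %d, excluded %s", len(kept), dict(counts)
        )
    return kept
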