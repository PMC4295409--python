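"""Decomposition of complete prevalence into phases of care.

At any mid-year a prevalent case occupies exactly one phase of the
survivorship trajectory:

* **initial care** — the first 12 months after diagnosis, excluding cases
  who die of the cancer within that year,
* **post-treatment monitoring** — after initial care, before the long-term
  cutoff (default 10 years since diagnosis),
* **long-term survivor** — at or beyond the cutoff,
* **last year of life** — the final 12 months before a cancer death,
  taking precedence over the duration bands (cases with survival shorter
  than 12 months are in this phase from diagnosis),
* **treatment for metastases / second cancer** — a sub-phase carved out of
  monitoring and long-term survivors for those needing renewed treatment
  after tumour spread or a second primary, projected by applying
  reference-year event proportions to the parent phases.

Phase counts are mutually exclusive and sum exactly to total prevalence for
every year and age group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prevalence_engine import MortalitySeries, PrevalenceSurface
from .registry_model import AnalysisConfig, CaseRecord

logger = logging.getLogger(__name__)

PHASES = ("initial", "monitoring", "long_term", "last_year", "subphase_event")


class PhaseTable:
    """Phase x age group x year counts with exact conservation."""

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig):
        required = {"year", "age_group", "phase", "count"}
        if not required.issubset(data.columns):
            raise ValueError(f"PhaseTable needs columns {sorted(required)}")
        if (data["count"] < -1e-9).any():
            raise ValueError("negative phase count")
        self.data = data.reset_index(drop=True)
        self.config = config

    def pivot(self, year: int) -> pd.DataFrame:
        d = self.data[self.data["year"] == year]
        if d.empty:
            raise ValueError(f"year {year} not in phase table")
        return d.pivot(index="phase", columns="age_group", values="count").reindex(
            [p for p in PHASES if p in d["phase"].unique()]
        )

    def phase_total(self, year: int, phase: str) -> float:
        d = self.data
        return float(
            d[(d["year"] == year) & (d["phase"] == phase)]["count"].sum()
        )

    def total(self, year: int) -> float:
        return float(self.data[self.data["year"] == year]["count"].sum())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig) -> "PhaseTable":
        return cls(pd.read_csv(path), config)


def decompose_phases(
    surface: PrevalenceSurface,
    deaths: MortalitySeries | None,
    config: AnalysisConfig,
    years,
) -> PhaseTable:
    """Split the prevalence surface into the four primary phases.

    The last-year-of-life count at mid-year ``t`` is the expected number of
    prevalent cases dying of the cancer before the next mid-year.  The
    surface carries that expectation per (age, duration) stratum
    (``excess_next``); when a mortality series is supplied its value for
    calendar year ``t + 1`` rescales the stratum allocations, so a projected
    mortality trend can drive the future last-year counts.  Allocations are
    clipped at the stratum's prevalence (with a warning) and the duration
    bands then receive the remainder, so phases sum to total prevalence
    exactly.
    """
    cutoff = config.long_term_cutoff_years
    rows = []
    for t in sorted(int(y) for y in years):
        ti = surface._yi(t)
        n = surface.values[ti]          # (age, duration)
        e = surface.excess_next[ti].copy()
        if deaths is not None:
            target = deaths.expected_at(t + 1)
            e_tot = e.sum()
            if target is not None and e_tot > 0:
                e *= target / e_tot
        if np.any(e > n + 1e-9):
            logger.warning(
                "year %d: last-year allocation exceeded stratum prevalence; clipped",
                t,
            )
        e = np.minimum(e, n)
        rest = n - e
        for gi, (lo, hi) in enumerate(config.survival_age_groups):
            m = (surface.ages >= lo) & (surface.ages <= hi)
            label = config.age_group_label(gi)
            rows += [
                {"year": t, "age_group": label, "phase": "initial",
                 "count": float(rest[m, 0].sum())},
                {"year": t, "age_group": label, "phase": "monitoring",
                 "count": float(rest[m, 1:cutoff].sum())},
                {"year": t, "age_group": label, "phase": "long_term",
                 "count": float(rest[m, cutoff:].sum())},
                {"year": t, "age_group": label, "phase": "last_year",
                 "count": float(e[m].sum())},
            ]
    return PhaseTable(pd.DataFrame(rows), config)


@dataclass(frozen=True)
class EventProportions:
    """Reference-year fractions of monitoring / long-term phase members who
    present a qualifying metastasis or second primary and survive it a year."""

    p_monitoring: float
    p_long_term: float
    reference_year: int
    n_monitoring: int = 0
    n_long_term: int = 0

    def __post_init__(self):
        for p in (self.p_monitoring, self.p_long_term):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event proportions must lie in [0, 1]")


def _phase_at(case: CaseRecord, year: int, config: AnalysisConfig) -> str | None:
    """Registry-record phase of a case at mid-year ``year`` (None if not prevalent)."""
    if case.year_dx > year:
        return None
    if case.year_death is not None and case.year_death <= year:
        return None
    if case.age_dx + (year - case.year_dx) > config.age_max:
        return None
    if (
        case.year_death == year + 1
        and case.cause_death == "cancer"
    ):
        return "last_year"
    d = year - case.year_dx
    if d == 0:
        return "initial"
    if d < config.long_term_cutoff_years:
        return "monitoring"
    return "long_term"


def _qualifying_event_in(case: CaseRecord, year: int) -> bool:
    """Any metastasis (outside the post-diagnosis lag) or second primary in ``year``.

    The metastasis lag rule — notifications within the first 120 days are
    part of the initial tumour — is applied at the data's annual resolution
    by discarding metastasis notifications from the diagnosis year itself.
    """
    for ey, etype in case.event_years:
        if ey != year:
            continue
        if etype == "metastasis" and ey == case.year_dx:
            continue
        return True
    return False


def estimate_event_proportions(
    cases: list[CaseRecord], config: AnalysisConfig
) -> EventProportions:
    """Proportion of reference-year phase members with a qualifying event.

    The numerator counts members of the monitoring (resp. long-term) phase in
    the reference year who had a metastasis/second-primary notification that
    year *and* survived at least one further year (those dying within a year
    of the event belong to the last-year-of-life phase instead).  Requires at
    least one year of follow-up after the reference year.
    """
    ref = config.subphase_reference_year
    if ref + 1 > config.obs_year_max:
        raise ValueError(
            "reference year needs >= 1 year of subsequent follow-up within "
            "the observation window"
        )
    denom = {"monitoring": 0, "long_term": 0}
    numer = {"monitoring": 0, "long_term": 0}
    for c in cases:
        phase = _phase_at(c, ref, config)
        if phase not in denom:
            continue
        denom[phase] += 1
        if _qualifying_event_in(c, ref):
            survived = c.year_death is None or c.year_death > ref + 1
            if survived:
                numer[phase] += 1
    for phase, n in denom.items():
        if n == 0:
            raise ValueError(f"empty {phase} phase in reference year {ref}")
    return EventProportions(
        p_monitoring=numer["monitoring"] / denom["monitoring"],
        p_long_term=numer["long_term"] / denom["long_term"],
        reference_year=ref,
        n_monitoring=numer["monitoring"],
        n_long_term=numer["long_term"],
    )


def apply_subphase(
    table: PhaseTable, props: EventProportions, years
) -> PhaseTable:
    """Carve the metastasis/second-cancer sub-phase out of its parent phases.

    For each (year, age group) cell in ``years``, ``round(p * parent)`` cases
    move from the monitoring and long-term phases into the sub-phase; the
    moved counts are subtracted from the parents, so totals are conserved
    exactly.  Other years pass through unchanged with a zero sub-phase.
    """
    years = {int(y) for y in years}
    df = table.data.copy()
    pivot = df.pivot_table(
        index=["year", "age_group"], columns="phase", values="count", fill_value=0.0
    )
    rows = []
    for (year, age_group), r in pivot.iterrows():
        moved_m = moved_l = 0.0
        if year in years:
            moved_m = float(np.round(props.p_monitoring * r.get("monitoring", 0.0)))
            moved_l = float(np.round(props.p_long_term * r.get("long_term", 0.0)))
            moved_m = min(moved_m, r.get("monitoring", 0.0))
            moved_l = min(moved_l, r.get("long_term", 0.0))
        out = dict(r)
        out["monitoring"] = r.get("monitoring", 0.0) - moved_m
        out["long_term"] = r.get("long_term", 0.0) - moved_l
        out["subphase_event"] = moved_m + moved_l
        for phase, count in out.items():
            rows.append(
                {"year": year, "age_group": age_group, "phase": phase, "count": count}
            )
    return PhaseTable(pd.DataFrame(rows), table.config)


# ---------------------------------------------------------------------------
# Derived display statistics


def percent_change(n_a: float, n_b: float) -> float:
    """Percent change from ``n_a`` to ``n_b``; undefined (NaN) when n_a = 0."""
    if n_a == 0:
        return float("nan")
    return (n_b - n_a) / n_a * 100.0


def annual_linear_rate(n_a: float, n_b: float, year_a: int, year_b: int) -> float:
    """Average annual linear percent increase between two years."""
    if year_b == year_a:
        raise ValueError("years must differ")
    return percent_change(n_a, n_b) / (year_b - year_a)


def summary_statistics(
    totals: dict[int, float], year_a: int, year_b: int
) -> dict[str, float]:
    """Percent change and average annual linear rate between two report years."""
    n_a, n_b = totals[year_a], totals[year_b]
    return {
        "year_a": year_a,
        "year_b": year_b,
        "n_a": n_a,
        "n_b": n_b,
        "percent_change": percent_change(n_a, n_b),
        "annual_linear_rate": annual_linear_rate(n_a, n_b, year_a, year_b),
    }


def active_treatment_share(table: PhaseTable, year: int) -> float:
    """Share of prevalent cases needing active treatment: initial + sub-phase."""
    total = table.total(year)
    if total == 0:
        return float("nan")
    active = table.phase_total(year, "initial") + table.phase_total(
        year, "subphase_event"
    )
    return 100.0 * active / total
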