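"""Synthetic cancer-registry generator with known ground truth.

Real registry extracts of this kind are confidential, so the pipeline is
exercised against a generator that emulates the statistical structure the
analysis assumes:

* diagnosis counts per (age, year) cell are Poisson with mean
  ``exp(APC linear predictor) x person-years`` — the same polynomial
  age+cohort log-linear family the incidence module fits,
* each case's net (excess) time to cancer death follows a mixture cure law:
  with probability ``c`` the case is statistically cured and can never die of
  the cancer; otherwise the net death time is Weibull,
* background (other-cause) death times are drawn from the all-cause life
  table along the diagnosis-cohort diagonal, independently of the net cancer
  process — the standard relative-survival independence assumption,
* metastasis and second-primary notifications arrive with constant annual
  hazards among survivors.

Diagnoses occur at mid-year.  Annual follow-up intervals run mid-year to
mid-year, and a death in interval ``j`` is recorded in calendar year
``year_dx + j``; the estimation modules use the same convention, so the
generator's truth is exactly the quantity they target.

The generator simulates diagnoses from ``config.backcast_year_min`` onward
(with population, life table and survival parameters frozen at their
earliest observed-year values before the observation window) so that
complete prevalence inside the window has its full long-duration tail, but
the emitted *registry* extract only contains cases diagnosed inside the
observation window, as a real registry would.  The uncensored truth for
every simulated case — including pre-window diagnoses — is retained
separately and drives the direct-counting oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .apc_incidence import APCModelSpec, DEFAULT_TRANSFORM
from .registry_model import (
    AnalysisConfig,
    CaseRecord,
    LifeTable,
    PopulationTable,
    write_cases,
    write_lifetable,
    write_population,
)

#: Sentinel "death year" for cases that never die within the simulated horizon.
NEVER = 9999


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters; defaults mirror the study conditions.

    The APC coefficients live on the same transformed covariate scale as the
    incidence module (age centred at 50 / 20, cohort at 1930 / 40), so fitted
    coefficients are directly comparable with the truth.  Cure and Weibull
    parameters are per survival age group, with the stated per-year trends on
    the logit (cure) and log (Weibull scale) scales, anchored at
    ``trend_ref_year``; before the observation window they are frozen at
    their first-observed-year values.

    Defaults are sized to produce roughly 90,000 cases over a 36-year
    observation window (the scale of the study cohort) with late-2000s
    5-year net survival near 0.9 and a cure fraction around 0.6-0.75.
    """

    apc_spec: APCModelSpec = field(default_factory=lambda: APCModelSpec(3, 0, 3))
    # [intercept, age^1..3, cohort^1..3] -> rate per person-year at age 50,
    # cohort 1930 of exp(-6.45) ~ 1.6 per 1000.
    apc_coefficients: tuple[float, ...] = (-6.45, 1.10, -0.55, 0.06, 0.55, 0.0, 0.03)
    # cure fraction logit intercepts per age group (18-49, 50-69, 70-84) at
    # trend_ref_year, plus a common logit slope per calendar year.
    cure_logit_intercept: tuple[float, ...] = (0.60, 0.80, 0.40)
    cure_logit_slope: float = 0.025
    # Weibull net-survival law of the non-cured: log scale (1/years) at
    # trend_ref_year with a per-year trend, and shape per age group.
    weibull_log_scale: tuple[float, ...] = (-1.55, -1.60, -1.30)
    weibull_log_scale_slope: float = -0.005
    weibull_shape: tuple[float, ...] = (1.2, 1.1, 1.0)
    trend_ref_year: int = 1990
    # Gompertz background mortality qx(a, y) = a0 exp(b a) exp(-r (y - ref)),
    # capped at qx_cap.
    gompertz_a: float = 3.0e-5
    gompertz_b: float = 0.095
    mortality_improvement: float = 0.006
    qx_cap: float = 0.95
    # annual hazards of subsequent metastasis / second primary among survivors
    metastasis_hazard: float = 0.012
    second_primary_hazard: float = 0.008
    # population: total women aged 18-84 in the first observed year, exponential
    # growth per year, and an age shape flat to shape_knee then decaying.
    pop_total_first_year: float = 1.55e6
    pop_growth: float = 0.012
    pop_shape_knee: int = 45
    pop_shape_decay: float = 28.0
    seed: int = 20140936

    def __post_init__(self):
        n_groups = len(self.cure_logit_intercept)
        if not (len(self.weibull_log_scale) == len(self.weibull_shape) == n_groups):
            raise ValueError("per-age-group parameter tuples differ in length")
        if any(g <= 0 for g in self.weibull_shape):
            raise ValueError("Weibull shapes must be positive")
        if min(self.metastasis_hazard, self.second_primary_hazard) < 0:
            raise ValueError("event hazards must be nonnegative")

    # -- true laws ----------------------------------------------------------

    def _trend_year(self, year_dx, config: AnalysisConfig):
        """Survival parameters are frozen before the observation window."""
        return np.maximum(np.asarray(year_dx, dtype=float), config.obs_year_min)

    def true_cure_fraction(self, group: int, year_dx, config: AnalysisConfig):
        y = self._trend_year(year_dx, config)
        logit = self.cure_logit_intercept[group] + self.cure_logit_slope * (
            y - self.trend_ref_year
        )
        return 1.0 / (1.0 + np.exp(-logit))

    def true_weibull_scale(self, group: int, year_dx, config: AnalysisConfig):
        y = self._trend_year(year_dx, config)
        return np.exp(
            self.weibull_log_scale[group]
            + self.weibull_log_scale_slope * (y - self.trend_ref_year)
        )

    def true_net_survival(self, d, group: int, year_dx, config: AnalysisConfig):
        """Mixture-cure net survival RS(d) = c + (1-c) exp(-(lam d)^gamma)."""
        d = np.asarray(d, dtype=float)
        c = self.true_cure_fraction(group, year_dx, config)
        lam = self.true_weibull_scale(group, year_dx, config)
        gam = self.weibull_shape[group]
        return c + (1.0 - c) * np.exp(-np.power(lam * d, gam))

    def true_log_rate(self, ages, years):
        return self.apc_spec.linear_predictor(
            self.apc_coefficients, ages, years, DEFAULT_TRANSFORM
        )


@dataclass
class SimulatedRegistry:
    """A generated registry extract plus the generator's uncensored truth."""

    cases: list[CaseRecord]
    population: PopulationTable
    lifetable: LifeTable
    truth: pd.DataFrame  # one row per simulated case, incl. pre-window diagnoses
    params: SimulationParams
    config: AnalysisConfig

    def write(self, outdir) -> dict[str, Path]:
        """Write the registry CSVs plus a truth.json of generating parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cases": outdir / "cases.csv",
            "events": outdir / "events.csv",
            "population": outdir / "population.csv",
            "lifetable": outdir / "lifetable.csv",
            "truth": outdir / "truth.json",
        }
        write_cases(self.cases, paths["cases"], paths["events"])
        write_population(self.population, paths["population"])
        write_lifetable(self.lifetable, paths["lifetable"])
        payload = asdict(self.params)
        payload["apc_spec"] = self.params.apc_spec.label
        with open(paths["truth"], "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return paths


def make_population(params: SimulationParams, config: AnalysisConfig) -> PopulationTable:
    """Smooth synthetic female population, ages 0-85 x observation years."""
    ages = np.arange(0, 86)
    years = np.arange(config.obs_year_min, config.obs_year_max + 1)
    shape = np.where(
        ages <= params.pop_shape_knee,
        1.0,
        np.exp(-(ages - params.pop_shape_knee) / params.pop_shape_decay),
    )
    base = shape / shape[config.age_min : config.age_max + 1].sum()
    base = base * params.pop_total_first_year
    growth = (1.0 + params.pop_growth) ** (years - config.obs_year_min)
    return PopulationTable(np.outer(base, growth), ages, years)


def make_lifetable(params: SimulationParams, config: AnalysisConfig) -> LifeTable:
    ages = np.arange(0, 86)
    years = np.arange(config.obs_year_min, config.obs_year_max + 1)
    aa, yy = np.meshgrid(ages, years, indexing="ij")
    qx = params.gompertz_a * np.exp(params.gompertz_b * aa)
    qx = qx * np.exp(-params.mortality_improvement * (yy - params.trend_ref_year))
    return LifeTable(np.clip(qx, 0.0, params.qx_cap), ages, years)


def _draw_background_interval(
    rng: np.random.Generator,
    lifetable: LifeTable,
    age_dx: int,
    year_dx: int,
    n: int,
    horizon: int,
) -> np.ndarray:
    """Death interval (1-based) from the life-table diagonal; > horizon -> never.

    The discrete law matches the expected-survival factor used downstream:
    P(surviving the first k intervals) = prod_{m<k} (1 - qx(age+m, year+m)),
    with edge clamping supplied by the life table itself.
    """
    k = np.arange(horizon)
    surv = np.concatenate(
        [[1.0], np.cumprod(1.0 - lifetable.qx(age_dx + k, year_dx + k))]
    )
    u = rng.random(n)
    # smallest j with surv[j] < u  (death during interval j)
    j = np.searchsorted(-surv, -u, side="right")
    return np.where(j > horizon, NEVER, j).astype(np.int64)


def simulate_registry(
    params: SimulationParams, config: AnalysisConfig
) -> SimulatedRegistry:
    """Generate a registry extract plus per-case uncensored truth.

    Reproducible: the same (params, config) pair gives identical output.
    """
    rng = np.random.default_rng(params.seed)
    population = make_population(params, config)
    lifetable = make_lifetable(params, config)
    if population.values.sum() <= 0:
        raise ValueError("degenerate population: zero person-years everywhere")

    ages = np.arange(config.age_min, config.age_max + 1)
    sim_years = np.arange(config.backcast_year_min, config.obs_year_max + 1)
    aa, yy = np.meshgrid(ages, sim_years, indexing="ij")
    log_rate = params.true_log_rate(aa.ravel(), yy.ravel()).reshape(aa.shape)
    py = population.person_years(aa, yy)  # frozen at first year before the window
    mean = np.where(np.isneginf(log_rate), 0.0, np.exp(log_rate) * py)
    counts = rng.poisson(mean)

    # horizon long enough that only effectively-immortal cases exceed it
    horizon = (config.proj_year_max - config.backcast_year_min) + 40

    met_rate = params.metastasis_hazard
    sp_rate = params.second_primary_hazard
    lag_years = config.metastasis_lag_days / 365.25

    records: list[dict] = []
    for ai, age in enumerate(ages):
        group = config.age_group_index(int(age))
        for yi, year in enumerate(sim_years):
            n = int(counts[ai, yi])
            if n == 0:
                continue
            c = params.true_cure_fraction(group, year, config)
            lam = params.true_weibull_scale(group, year, config)
            gam = params.weibull_shape[group]
            cured = rng.random(n) < c
            t_cancer = np.full(n, np.inf)
            n_uncured = int((~cured).sum())
            if n_uncured:
                u = rng.random(n_uncured)
                t_cancer[~cured] = np.power(-np.log(u), 1.0 / gam) / lam
            j_cancer = np.where(np.isinf(t_cancer), NEVER, np.ceil(t_cancer)).astype(
                np.int64
            )
            j_cancer = np.maximum(j_cancer, 1)
            j_bg = _draw_background_interval(rng, lifetable, age, year, n, horizon)
            j_obs = np.minimum(j_cancer, j_bg)
            is_cancer = j_cancer <= j_bg
            death_year = np.where(j_obs >= NEVER, NEVER, year + j_obs)

            # first metastasis / second primary among survivors (exponential
            # waiting times from mid-year of diagnosis, subject to the lag rule
            # for metastases; events must precede death)
            t_death = np.where(j_obs >= NEVER, np.inf, j_obs.astype(float))
            t_met = rng.exponential(1.0 / met_rate, n) if met_rate > 0 else np.full(n, np.inf)
            t_met = np.where(t_met < lag_years, np.inf, t_met)
            t_sp = rng.exponential(1.0 / sp_rate, n) if sp_rate > 0 else np.full(n, np.inf)
            met_year = np.where(t_met < t_death, np.floor(year + 0.5 + t_met), NEVER)
            sp_year = np.where(t_sp < t_death, np.floor(year + 0.5 + t_sp), NEVER)

            for m in range(n):
                records.append(
                    {
                        "age_dx": int(age),
                        "year_dx": int(year),
                        "true_year_death": int(death_year[m]),
                        "true_cause": (
                            "none"
                            if death_year[m] >= NEVER
                            else ("cancer" if is_cancer[m] else "other")
                        ),
                        "cured": bool(cured[m]),
                        "t_cancer": float(t_cancer[m]) if np.isfinite(t_cancer[m]) else np.nan,
                        "met_year": int(met_year[m]),
                        "sp_year": int(sp_year[m]),
                    }
                )

    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "age_dx", "year_dx", "true_year_death", "true_cause",
            "cured", "t_cancer", "met_year", "sp_year",
        ],
    )
    truth.insert(0, "case_id", [f"S{i:06d}" for i in range(len(truth))])

    cases = _registry_view(truth, config)
    return SimulatedRegistry(cases, population, lifetable, truth, params, config)


def _registry_view(truth: pd.DataFrame, config: AnalysisConfig) -> list[CaseRecord]:
    """Censor the truth at the end of follow-up and drop pre-window diagnoses."""
    cases = []
    inwin = truth[truth["year_dx"] >= config.obs_year_min]
    for row in inwin.itertuples(index=False):
        dead = row.true_year_death <= config.obs_year_max
        events = []
        for y, etype in ((row.met_year, "metastasis"), (row.sp_year, "second_primary")):
            if y < NEVER and y <= config.obs_year_max:
                events.append((int(y), etype))
        cases.append(
            CaseRecord(
                case_id=row.case_id,
                age_dx=int(row.age_dx),
                year_dx=int(row.year_dx),
                vital_status="dead" if dead else "alive",
                year_death=int(row.true_year_death) if dead else None,
                cause_death=row.true_cause if dead else None,
                event_years=tuple(sorted(events)),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Direct-counting oracles (ground truth for the estimation modules)


def _alive_at(truth: pd.DataFrame, year: int) -> pd.Series:
    return (truth["year_dx"] <= year) & (truth["true_year_death"] > year)


def _check_horizon(truth: pd.DataFrame, year: int, config: AnalysisConfig) -> None:
    if year < config.backcast_year_min or year > config.obs_year_max:
        raise ValueError(
            f"oracle year {year} outside simulated horizon "
            f"[{config.backcast_year_min}, {config.obs_year_max}]"
        )


def oracle_prevalence(
    truth: pd.DataFrame, year: int, config: AnalysisConfig
) -> pd.DataFrame:
    """Count cases truly alive at mid-year of ``year``, by attained-age group
    and duration band (initial / monitoring / long-term bands).

    A case diagnosed in year y who dies in year y+k is prevalent at the
    mid-years of y .. y+k-1 only (death at mid-year of y+k).  Only attained
    ages inside the analysed range count.
    """
    _check_horizon(truth, year, config)
    cutoff = config.long_term_cutoff_years
    bands = [(0, 0), (1, cutoff - 1), (cutoff, 10**6)]
    band_labels = ["0", f"1-{cutoff - 1}", f"{cutoff}+"]

    alive = truth[_alive_at(truth, year)].copy()
    alive["attained_age"] = alive["age_dx"] + (year - alive["year_dx"])
    alive = alive[
        (alive["attained_age"] >= config.age_min)
        & (alive["attained_age"] <= config.age_max)
    ]
    alive["duration"] = year - alive["year_dx"]

    rows = []
    for gi, (lo, hi) in enumerate(config.survival_age_groups):
        in_g = (alive["attained_age"] >= lo) & (alive["attained_age"] <= hi)
        for (dlo, dhi), blabel in zip(bands, band_labels):
            n = int((in_g & (alive["duration"] >= dlo) & (alive["duration"] <= dhi)).sum())
            rows.append(
                {
                    "age_group": config.age_group_label(gi),
                    "duration_band": blabel,
                    "count": n,
                }
            )
    return pd.DataFrame(rows)


def oracle_phase_counts(
    truth: pd.DataFrame, year: int, config: AnalysisConfig
) -> dict[str, int]:
    """Per-case phase assignment from the uncensored truth.

    A prevalent case is in the last-year-of-life phase iff it truly dies of
    the cancer at the next mid-year; otherwise the phase is the duration
    band (initial care at duration 0, monitoring before the long-term
    cutoff, long-term survivor at or beyond it).
    """
    _check_horizon(truth, year, config)
    alive = truth[_alive_at(truth, year)].copy()
    alive["attained_age"] = alive["age_dx"] + (year - alive["year_dx"])
    alive = alive[
        (alive["attained_age"] >= config.age_min)
        & (alive["attained_age"] <= config.age_max)
    ]
    duration = year - alive["year_dx"]
    last_year = (alive["true_year_death"] == year + 1) & (
        alive["true_cause"] == "cancer"
    )
    counts = {
        "last_year": int(last_year.sum()),
        "initial": int((~last_year & (duration == 0)).sum()),
        "monitoring": int(
            (~last_year & (duration >= 1) & (duration < config.long_term_cutoff_years)).sum()
        ),
        "long_term": int(
            (~last_year & (duration >= config.long_term_cutoff_years)).sum()
        ),
    }
    counts["total"] = sum(counts.values())
    return counts


def oracle_cancer_deaths(truth: pd.DataFrame, years) -> pd.Series:
    """True cancer deaths per calendar year (uncensored truth)."""
    dead = truth[truth["true_cause"] == "cancer"]
    counts = dead["true_year_death"].value_counts()
    years = list(years)
    return pd.Series([int(counts.get(y, 0)) for y in years], index=years, name="deaths")
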