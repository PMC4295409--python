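"""Age-period-cohort Poisson modelling of incidence rates.

Incidence counts per (single year of age) x (calendar year) cell are modelled
as Poisson with a log link and a log person-years offset,

    log rate(a, p) = alpha_0 + sum_i alpha_i a'^i + sum_j pi_j p'^j
                     + sum_k gamma_k c'^k,        c = p - a,

with polynomial age, period and cohort terms.  The nine candidate models of
the analysis (labelled ``APCdad_p d_c`` with digits = polynomial degrees) all
use period degree 0, i.e. age + cohort polynomials only, which sidesteps the
classic APC identification problem; the fitter nevertheless supports a
nonzero period degree.  Model comparison uses the deviance against the
saturated model (the likelihood-ratio statistic).

Covariates are centred and scaled before polynomial expansion (cubic terms in
raw calendar years are numerically hopeless); coefficients live on the
transformed scale and the transform is stored with every fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry_model import AnalysisConfig, CaseRecord, PopulationTable

logger = logging.getLogger(__name__)

#: Model labels considered for selection, in the conventional order.
CANDIDATE_LABELS = (
    "APC101", "APC102", "APC201", "APC202", "APC103",
    "APC301", "APC203", "APC302", "APC303",
)


@dataclass(frozen=True)
class CovariateTransform:
    """Affine rescaling applied to age/period/cohort before powers are taken."""

    age_center: float = 50.0
    age_scale: float = 20.0
    period_center: float = 1990.0
    period_scale: float = 20.0
    cohort_center: float = 1930.0
    cohort_scale: float = 40.0

    def age(self, a):
        return (np.asarray(a, dtype=float) - self.age_center) / self.age_scale

    def period(self, p):
        return (np.asarray(p, dtype=float) - self.period_center) / self.period_scale

    def cohort(self, c):
        return (np.asarray(c, dtype=float) - self.cohort_center) / self.cohort_scale


DEFAULT_TRANSFORM = CovariateTransform()


@dataclass(frozen=True)
class APCModelSpec:
    """Polynomial degrees for the age, period and cohort terms."""

    deg_age: int
    deg_period: int
    deg_cohort: int

    def __post_init__(self):
        if not (1 <= self.deg_age <= 3 and 0 <= self.deg_period <= 3 and 0 <= self.deg_cohort <= 3):
            raise ValueError(f"unsupported polynomial degrees {self!r}")

    @property
    def label(self) -> str:
        return f"APC{self.deg_age}{self.deg_period}{self.deg_cohort}"

    @classmethod
    def from_label(cls, label: str) -> "APCModelSpec":
        digits = label.removeprefix("APC")
        if len(digits) != 3 or not digits.isdigit():
            raise ValueError(f"malformed APC model label {label!r}")
        return cls(int(digits[0]), int(digits[1]), int(digits[2]))

    @property
    def n_params(self) -> int:
        return 1 + self.deg_age + self.deg_period + self.deg_cohort

    def is_nested_in(self, other: "APCModelSpec") -> bool:
        return (
            self.deg_age <= other.deg_age
            and self.deg_period <= other.deg_period
            and self.deg_cohort <= other.deg_cohort
        )

    def design_matrix(self, ages, years, transform: CovariateTransform = DEFAULT_TRANSFORM):
        """Design matrix columns: intercept, age powers, period powers, cohort powers."""
        ages = np.asarray(ages, dtype=float)
        years = np.asarray(years, dtype=float)
        x = transform.age(ages)
        p = transform.period(years)
        z = transform.cohort(years - ages)
        cols = [np.ones_like(x)]
        cols += [x**i for i in range(1, self.deg_age + 1)]
        cols += [p**j for j in range(1, self.deg_period + 1)]
        cols += [z**k for k in range(1, self.deg_cohort + 1)]
        return np.column_stack(cols)

    def linear_predictor(self, coefficients, ages, years,
                         transform: CovariateTransform = DEFAULT_TRANSFORM):
        """log rate per person-year at the given (age, year) points."""
        beta = np.asarray(coefficients, dtype=float)
        if beta.size != self.n_params:
            raise ValueError(
                f"{self.label} needs {self.n_params} coefficients, got {beta.size}"
            )
        ages = np.asarray(ages, dtype=float)
        years = np.asarray(years, dtype=float)
        shape = np.broadcast(ages, years).shape
        eta = self.design_matrix(
            np.broadcast_to(ages, shape).ravel(),
            np.broadcast_to(years, shape).ravel(),
            transform,
        ) @ beta
        return eta.reshape(shape) if shape else float(eta[0])


def nine_model_specs() -> list[APCModelSpec]:
    """The nine candidate age+cohort models (period degree 0 throughout)."""
    return [APCModelSpec.from_label(lbl) for lbl in CANDIDATE_LABELS]


class IncidenceTable:
    """Diagnosis counts and person-years on an (age x calendar year) grid."""

    def __init__(self, dx_count: np.ndarray, person_years: np.ndarray,
                 ages: np.ndarray, years: np.ndarray):
        dx_count = np.asarray(dx_count, dtype=float)
        person_years = np.asarray(person_years, dtype=float)
        if dx_count.shape != person_years.shape:
            raise ValueError("count and person-years grids differ in shape")
        if np.any((dx_count > 0) & (person_years <= 0)):
            raise ValueError("cases observed in a cell with no person-years")
        self.dx_count = dx_count
        self.person_years = person_years
        self.ages = np.asarray(ages, dtype=int)
        self.years = np.asarray(years, dtype=int)

    @property
    def total_cases(self) -> int:
        return int(round(self.dx_count.sum()))

    def long(self) -> pd.DataFrame:
        aa, yy = np.meshgrid(self.ages, self.years, indexing="ij")
        return pd.DataFrame(
            {
                "age": aa.ravel(),
                "year": yy.ravel(),
                "dx_count": self.dx_count.ravel(),
                "person_years": self.person_years.ravel(),
            }
        )


def tabulate_incidence(
    cases: list[CaseRecord], population: PopulationTable, config: AnalysisConfig
) -> IncidenceTable:
    """Count diagnoses per (age, year) cell against mid-year person-years."""
    ages = np.arange(config.age_min, config.age_max + 1)
    years = np.arange(config.obs_year_min, config.obs_year_max + 1)
    counts = np.zeros((ages.size, years.size))
    for c in cases:
        ai = c.age_dx - config.age_min
        yi = c.year_dx - config.obs_year_min
        if not (0 <= ai < ages.size and 0 <= yi < years.size):
            raise ValueError(
                f"case {c.case_id} at (age {c.age_dx}, year {c.year_dx}) "
                "falls outside the configured grid; filter cases first"
            )
        counts[ai, yi] += 1
    if population.age_min > config.age_min or population.age_max < config.age_max:
        raise ValueError(
            f"population table covers ages {population.age_min}-{population.age_max}, "
            f"needed {config.age_min}-{config.age_max}"
        )
    if population.year_min > config.obs_year_min or population.year_max < config.obs_year_max:
        raise ValueError("population table does not cover the observation years")
    aa, yy = np.meshgrid(ages, years, indexing="ij")
    py = population.person_years(aa, yy)
    return IncidenceTable(counts, py, ages, years)


@dataclass
class APCFit:
    """A fitted APC Poisson model.

    ``deviance`` is the likelihood-ratio statistic against the saturated
    model; ``coefficients`` (and ``se``) are on the transformed covariate
    scale described by ``transform``.
    """

    spec: APCModelSpec
    coefficients: np.ndarray
    se: np.ndarray
    deviance: float
    df_resid: int
    n_cells: int
    transform: CovariateTransform = field(default_factory=CovariateTransform)

    def fitted_rate(self, ages, years):
        """Incidence rate per person-year; strictly positive by construction."""
        eta = self.spec.linear_predictor(self.coefficients, ages, years, self.transform)
        return np.exp(eta)

    def to_json(self, path) -> None:
        payload = {
            "label": self.spec.label,
            "coefficients": list(self.coefficients),
            "se": list(self.se),
            "deviance": self.deviance,
            "df_resid": self.df_resid,
            "n_cells": self.n_cells,
            "transform": self.transform.__dict__,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "APCFit":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            spec=APCModelSpec.from_label(payload["label"]),
            coefficients=np.asarray(payload["coefficients"]),
            se=np.asarray(payload["se"]),
            deviance=payload["deviance"],
            df_resid=payload["df_resid"],
            n_cells=payload["n_cells"],
            transform=CovariateTransform(**payload["transform"]),
        )


def fit_apc(
    table: IncidenceTable,
    spec: APCModelSpec,
    transform: CovariateTransform = DEFAULT_TRANSFORM,
    maxiter: int = 200,
) -> APCFit:
    """Maximum-likelihood Poisson fit with log person-years offset.

    Cells with zero person-years are dropped with a warning (they carry no
    information and an offset of -inf).  Non-convergence raises with the
    fitter's diagnostics.
    """
    df = table.long()
    keep = df["person_years"] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("fit_apc: dropping %d cells with zero person-years", n_dropped)
    df = df[keep]
    if df.empty:
        raise ValueError("incidence table has no cells with positive person-years")
    X = spec.design_matrix(df["age"].to_numpy(), df["year"].to_numpy(), transform)
    model = sm.GLM(
        df["dx_count"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=np.log(df["person_years"].to_numpy()),
    )
    res = model.fit(maxiter=maxiter, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"fit_apc({spec.label}): IRLS failed to converge after {maxiter} "
            f"iterations (deviance {res.deviance:.3g})"
        )
    return APCFit(
        spec=spec,
        coefficients=np.asarray(res.params),
        se=np.asarray(res.bse),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        n_cells=int(len(df)),
        transform=transform,
    )


def fit_candidate_models(
    table: IncidenceTable, transform: CovariateTransform = DEFAULT_TRANSFORM
) -> list[APCFit]:
    return [fit_apc(table, spec, transform) for spec in nine_model_specs()]


def model_selection_table(fits: list[APCFit]) -> pd.DataFrame:
    """Rank fits by deviance (ascending).  Selection is reported, not forced:
    the analysis pins its model on epidemiological grounds, so callers may
    override the front-runner."""
    if not fits:
        raise ValueError("no fits to rank")
    n_cells = {f.n_cells for f in fits}
    if len(n_cells) != 1:
        raise ValueError("fits were not computed on the same data grid")
    rows = [
        {
            "label": f.spec.label,
            "deviance": f.deviance,
            "df_resid": f.df_resid,
            "n_params": f.spec.n_params,
        }
        for f in fits
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["deviance", "n_params"])
        .reset_index(drop=True)
    )


def project_incidence(fit: APCFit, years, config: AnalysisConfig) -> pd.DataFrame:
    """Evaluate the fitted log-rate polynomial over ``years`` x analysed ages.

    Works both backward (before the fitting window) and forward: the cohort
    covariate extends naturally as year - age.  Returns a long frame with
    columns age, year, rate (per person-year).
    """
    years = np.asarray(list(years), dtype=int)
    ages = np.arange(config.age_min, config.age_max + 1)
    aa, yy = np.meshgrid(ages, years, indexing="ij")
    rate = fit.fitted_rate(aa.ravel(), yy.ravel())
    return pd.DataFrame({"age": aa.ravel(), "year": yy.ravel(), "rate": rate})


class RateSurface:
    """Dense (age x year) incidence-rate lookup built from a projection frame."""

    def __init__(self, frame: pd.DataFrame):
        pivot = frame.pivot(index="age", columns="year", values="rate")
        if pivot.isna().any().any():
            raise ValueError("rate surface is not rectangular")
        self.ages = pivot.index.to_numpy()
        self.years = pivot.columns.to_numpy()
        self.values = pivot.to_numpy()

    def rate(self, age, year):
        ai = np.asarray(age) - self.ages[0]
        yi = np.asarray(year) - self.years[0]
        if np.any(ai < 0) or np.any(ai >= self.ages.size):
            raise ValueError("requested age outside the rate surface")
        if np.any(yi < 0) or np.any(yi >= self.years.size):
            raise ValueError("requested year outside the rate surface")
        return self.values[ai, yi]
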