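"""Net (relative) survival: Pohar Perme tabulation, mixture cure model, surface.

Net survival — the survival patients would experience if the cancer were the
only cause of death — is estimated in two steps, as in the classic
registry-survival workflow:

1. :func:`tabulate_pohar_perme` computes an actuarial (annual-interval)
   Pohar Perme estimate per (age group at diagnosis) x (diagnosis period),
   weighting each subject by the inverse of her cumulative expected survival
   from the general-population life table.  The *cohort approach* is used: an
   interval is tabulated only from cases whose potential follow-up reaches
   the end of that interval, so the most recent period contributes only its
   fully observable early intervals.
2. :func:`fit_mixture_cure` fits a mixture cure model

       RS(t; g, y) = c(g, y) + (1 - c(g, y)) * exp(-(lambda(g, y) t)^gamma_g)

   to the tabulated values by inverse-variance weighted least squares, with
   the cure fraction linear in diagnosis year on the logit scale and the
   Weibull scale log-linear in diagnosis year.

The fitted model then defines a smooth survival surface over all diagnosis
years: frozen at the first observed year going backward (stationarity before
the window) and following the fitted trends going forward.

Net-survival estimates are not bounded above by 1: in strata where observed
mortality falls below expected mortality the tabulated value may slightly
exceed 1.  This is a property of the estimator, not an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .registry_model import AnalysisConfig, CaseRecord, LifeTable

logger = logging.getLogger(__name__)

#: floor for standard errors used as WLS weights (avoids infinite weight on
#: early intervals of large strata)
SE_FLOOR = 1e-3


class RelSurvTable:
    """Tabulated cumulative net survival by age group x period x interval."""

    COLUMNS = [
        "group_index", "age_group", "period_index", "period",
        "year_mid", "interval", "rs", "se", "n_at_risk",
    ]

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"RelSurvTable missing columns: {missing}")
        self.data = data.reset_index(drop=True)

    def stratum(self, group_index: int, period_index: int) -> pd.DataFrame:
        d = self.data
        return d[(d["group_index"] == group_index) & (d["period_index"] == period_index)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RelSurvTable":
        return cls(pd.read_csv(path))


def _death_interval(case: CaseRecord) -> int | None:
    """Annual follow-up interval (1-based, mid-year to mid-year) of death.

    A death recorded in calendar year ``year_dx + j`` is assigned to interval
    ``j`` (deaths in the diagnosis year itself fall in interval 1).
    """
    if case.year_death is None:
        return None
    return max(case.year_death - case.year_dx, 1)


def tabulate_pohar_perme(
    cases: list[CaseRecord], lifetable: LifeTable, config: AnalysisConfig
) -> RelSurvTable:
    """Actuarial Pohar Perme net survival with the cohort approach.

    For interval ``j`` of a stratum, each subject at risk is weighted by
    ``w_i = 1 / S_E,i(j-1)``, the inverse of her cumulative expected survival
    at the interval start.  With weighted deaths ``D'``, weighted at-risk
    ``N'`` and weighted expected deaths ``d* = sum w_i (1 - p*_ij)``
    (``p*_ij`` the subject's expected interval survival), the interval net
    survival factor is ``1 - (D' - d*) / N'`` and cumulative net survival is
    the product of factors.  With a zero life table this reduces exactly to
    the classic actuarial observed-survival estimator.

    Cohort approach: interval ``j`` uses only cases with
    ``year_dx + j <= obs_year_max``; under follow-up to the end of the window
    those cases are never censored inside the interval.
    """
    exp_surv_cache: dict[tuple[int, int], np.ndarray] = {}

    def cum_expected(age_dx: int, year_dx: int, j_max: int) -> np.ndarray:
        key = (age_dx, year_dx)
        arr = exp_surv_cache.get(key)
        if arr is None or arr.size < j_max + 1:
            k = np.arange(j_max)
            arr = np.concatenate(
                [[1.0], np.cumprod(1.0 - lifetable.qx(age_dx + k, year_dx + k))]
            )
            exp_surv_cache[key] = arr
        return arr

    rows = []
    for gi, (alo, ahi) in enumerate(config.survival_age_groups):
        for pi, (plo, phi) in enumerate(config.survival_periods):
            members = [
                c
                for c in cases
                if alo <= c.age_dx <= ahi and plo <= c.year_dx <= phi
            ]
            if not members:
                logger.warning(
                    "empty survival stratum: ages %d-%d, period %d-%d",
                    alo, ahi, plo, phi,
                )
                continue
            j_max = config.obs_year_max - plo
            age = np.array([c.age_dx for c in members])
            year = np.array([c.year_dx for c in members])
            jdeath = np.array(
                [j if (j := _death_interval(c)) is not None else np.iinfo(np.int64).max
                 for c in members],
                dtype=np.int64,
            )
            # cumulative expected survival per member, S_E,i(0..j_max)
            se_mat = np.empty((len(members), j_max + 1))
            for i in range(len(members)):
                se_mat[i] = cum_expected(int(age[i]), int(year[i]), j_max)[: j_max + 1]

            cum_rs = 1.0
            cum_var = 0.0
            for j in range(1, j_max + 1):
                potential = year + j <= config.obs_year_max  # cohort approach
                at_risk = potential & (jdeath >= j)
                if not np.any(at_risk):
                    break
                w = 1.0 / se_mat[at_risk, j - 1]
                pstar = se_mat[at_risk, j] / se_mat[at_risk, j - 1]
                died = jdeath[at_risk] == j
                Nw = w.sum()
                Dw = w[died].sum()
                dstar = (w * (1.0 - pstar)).sum()
                factor = 1.0 - (Dw - dstar) / Nw
                cum_rs *= factor
                n_die = int(died.sum())
                n_risk = int(at_risk.sum())
                if 0 < n_die < n_risk:
                    cum_var += n_die / (n_risk * (n_risk - n_die))
                rows.append(
                    {
                        "group_index": gi,
                        "age_group": config.age_group_label(gi),
                        "period_index": pi,
                        "period": f"{plo}-{phi}",
                        "year_mid": config.period_midpoint(pi),
                        "interval": j,
                        "rs": cum_rs,
                        "se": abs(cum_rs) * np.sqrt(cum_var),
                        "n_at_risk": Nw,
                    }
                )
    return RelSurvTable(pd.DataFrame(rows, columns=RelSurvTable.COLUMNS))


# ---------------------------------------------------------------------------
# Mixture cure model


@dataclass
class CureParams:
    """Fitted mixture-cure parameters per survival age group.

    For age group ``g`` and diagnosis year ``y``::

        logit c(g, y)      = cure_intercept[g] + cure_slope[g] * (y - ref_year)
        log lambda(g, y)   = scale_intercept[g] + scale_slope[g] * (y - ref_year)
        gamma(g)           = shape[g]

    ``boundary_flags[g]`` marks groups whose cure fraction was driven to a
    boundary of (0, 1) — the trend is then unreliable.
    """

    cure_intercept: np.ndarray
    cure_slope: np.ndarray
    scale_intercept: np.ndarray
    scale_slope: np.ndarray
    shape: np.ndarray
    ref_year: float
    boundary_flags: list[bool] = field(default_factory=list)
    residual_sumsq: list[float] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.cure_intercept)

    def cure_fraction(self, group: int, year):
        y = np.asarray(year, dtype=float)
        return expit(self.cure_intercept[group] + self.cure_slope[group] * (y - self.ref_year))

    def weibull_scale(self, group: int, year):
        y = np.asarray(year, dtype=float)
        return np.exp(self.scale_intercept[group] + self.scale_slope[group] * (y - self.ref_year))

    def rs(self, d, group: int, year):
        """Model net survival at duration d for diagnosis year ``year`` (no clamping)."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("duration must be nonnegative")
        c = self.cure_fraction(group, year)
        lam = self.weibull_scale(group, year)
        return c + (1.0 - c) * np.exp(-np.power(lam * d, self.shape[group]))

    def to_json(self, path) -> None:
        payload = {
            "cure_intercept": list(self.cure_intercept),
            "cure_slope": list(self.cure_slope),
            "scale_intercept": list(self.scale_intercept),
            "scale_slope": list(self.scale_slope),
            "shape": list(self.shape),
            "ref_year": self.ref_year,
            "boundary_flags": self.boundary_flags,
            "residual_sumsq": self.residual_sumsq,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CureParams":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            cure_intercept=np.asarray(p["cure_intercept"]),
            cure_slope=np.asarray(p["cure_slope"]),
            scale_intercept=np.asarray(p["scale_intercept"]),
            scale_slope=np.asarray(p["scale_slope"]),
            shape=np.asarray(p["shape"]),
            ref_year=p["ref_year"],
            boundary_flags=p["boundary_flags"],
            residual_sumsq=p["residual_sumsq"],
        )


def fit_mixture_cure(table: RelSurvTable, config: AnalysisConfig) -> CureParams:
    """Weighted least-squares fit of the mixture cure model per age group.

    Each age group is fitted independently on its tabulated (period,
    interval) values, weighted by inverse variance (standard errors floored
    at ``SE_FLOOR``).  The period is represented by its midpoint year.
    Requires at least two diagnosis periods per group; a cure fraction driven
    to a boundary of (0, 1) is flagged rather than silently accepted.
    """
    ref_year = 0.5 * (config.obs_year_min + config.obs_year_max)
    n_groups = len(config.survival_age_groups)
    ci, cs, si, ss, sh = (np.zeros(n_groups) for _ in range(5))
    flags: list[bool] = []
    rss: list[float] = []

    for gi in range(n_groups):
        d = table.data[table.data["group_index"] == gi]
        if d["period_index"].nunique() < 2:
            raise ValueError(
                f"age group {config.age_group_label(gi)}: need >= 2 diagnosis "
                "periods to identify a trend"
            )
        t = d["interval"].to_numpy(dtype=float)
        y = d["year_mid"].to_numpy(dtype=float) - ref_year
        rs_obs = d["rs"].to_numpy(dtype=float)
        w = 1.0 / np.maximum(d["se"].to_numpy(dtype=float), SE_FLOOR)

        def model(theta, t=t, y=y):
            a, b, u, v, s = theta
            c = expit(a + b * y)
            lam = np.exp(u + v * y)
            gam = np.exp(s)
            return c + (1.0 - c) * np.exp(-np.power(lam * t, gam))

        def resid(theta):
            return (model(theta) - rs_obs) * w

        # initial values: plateau from the deepest tabulated intervals
        tail = rs_obs[t >= min(t.max(), 15)]
        c0 = float(np.clip(np.median(tail) if tail.size else rs_obs.min(), 0.05, 0.95))
        theta0 = np.array([logit(c0), 0.0, np.log(0.2), 0.0, 0.0])
        sol = least_squares(resid, theta0, method="lm", max_nfev=20000)
        if not sol.success:
            raise RuntimeError(
                f"mixture cure fit failed for age group "
                f"{config.age_group_label(gi)}: {sol.message}; "
                f"residual norm {np.linalg.norm(sol.fun):.3g}"
            )
        a, b, u, v, s = sol.x
        boundary = bool(abs(a + b * np.median(y)) > 7.0)
        if boundary:
            logger.warning(
                "cure fraction at boundary for age group %s (logit %.1f)",
                config.age_group_label(gi), a,
            )
        ci[gi], cs[gi], si[gi], ss[gi], sh[gi] = a, b, u, v, np.exp(s)
        flags.append(boundary)
        rss.append(float(np.sum(sol.fun**2)))

    return CureParams(
        cure_intercept=ci, cure_slope=cs, scale_intercept=si, scale_slope=ss,
        shape=sh, ref_year=ref_year, boundary_flags=flags, residual_sumsq=rss,
    )


class SurvivalSurface:
    """RS(d; age group, diagnosis year) evaluator over the full analysis span.

    Diagnosis years before the observation window are frozen at the
    first-observed-year parameters (stationarity assumption); years after the
    window continue the fitted linear trends.  RS is nonincreasing in
    duration for fixed (group, year) and RS(0) = 1 identically.
    """

    def __init__(self, params: CureParams, config: AnalysisConfig):
        self.params = params
        self.config = config

    def _effective_year(self, year_dx):
        y = np.asarray(year_dx, dtype=float)
        if np.any(y > self.config.proj_year_max):
            raise ValueError("diagnosis year beyond the projection horizon")
        return np.maximum(y, self.config.obs_year_min)

    def __call__(self, d, group: int, year_dx):
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("duration must be nonnegative")
        return self.params.rs(d, group, self._effective_year(year_dx))

    def cure_fraction(self, group: int, year_dx):
        return self.params.cure_fraction(group, self._effective_year(year_dx))


def survival_surface(params: CureParams, config: AnalysisConfig) -> SurvivalSurface:
    return SurvivalSurface(params, config)
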