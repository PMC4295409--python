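"""Pohar Perme tabulation, mixture cure fitting and the survival surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from prevmod.net_survival import (
    CureParams,
    RelSurvTable,
    fit_mixture_cure,
    survival_surface,
    tabulate_pohar_perme,
)
from prevmod.registry_model import AnalysisConfig, CaseRecord, LifeTable
from prevmod.synthetic_registry import SimulationParams, make_lifetable

TOY = AnalysisConfig(
    obs_year_min=1998,
    obs_year_max=2007,
    proj_year_max=2010,
    survival_periods=((1998, 2002), (2003, 2007)),
    subphase_reference_year=2005,
)


def case(i, age=55, year=2000, death=None, cause="cancer"):
    return CaseRecord(
        case_id=f"t{i}", age_dx=age, year_dx=year,
        vital_status="dead" if death else "alive",
        year_death=death, cause_death=cause if death else None,
    )


def flat_lifetable(q, config=TOY):
    ages = np.arange(0, 106)
    years = np.arange(config.backcast_year_min, config.proj_year_max + 1)
    return LifeTable(np.full((ages.size, years.size), q), ages, years)


def classic_actuarial(cases, j_max, obs_year_max):
    """Independent life-table (actuarial) observed-survival oracle."""
    out = []
    cum = 1.0
    for j in range(1, j_max + 1):
        at_risk = [
            c for c in cases
            if c.year_dx + j <= obs_year_max
            and (c.year_death is None or max(c.year_death - c.year_dx, 1) >= j)
        ]
        if not at_risk:
            break
        deaths = sum(
            1 for c in at_risk
            if c.year_death is not None and max(c.year_death - c.year_dx, 1) == j
        )
        cum *= 1.0 - deaths / len(at_risk)
        out.append(cum)
    return out


class TestPoharPerme:
    def test_hand_computed_actuarial_toy(self):
        """With qx=0, the 4-case toy cohort reproduces hand life-table values.

        Deaths in follow-up years 1 and 3, two survivors: interval survivals
        3/4, 1, 2/3, 1, 1 -> cumulative 0.75, 0.75, 0.5, 0.5, 0.5.
        """
        cases = [
            case(1, year=2000, death=2001),
            case(2, year=2000, death=2003),
            case(3, year=2000),
            case(4, year=2000),
        ]
        tab = tabulate_pohar_perme(cases, flat_lifetable(0.0), TOY)
        got = tab.data.sort_values("interval")["rs"].to_numpy()
        np.testing.assert_allclose(got[:5], [0.75, 0.75, 0.5, 0.5, 0.5])

    def test_all_alive_zero_expected_mortality_gives_unity(self):
        cases = [case(i, year=1999) for i in range(10)]
        tab = tabulate_pohar_perme(cases, flat_lifetable(0.0), TOY)
        np.testing.assert_allclose(tab.data["rs"], 1.0)

    def test_cohort_approach_limits_intervals(self):
        """A case diagnosed in 2006 can only contribute one full interval."""
        cases = [case(1, year=2006)]
        tab = tabulate_pohar_perme(cases, flat_lifetable(0.0), TOY)
        assert tab.data["interval"].max() == 1

    def test_recovers_known_net_survival(self):
        """Simulated cohort with known 5-year net survival 0.80 (n = 10,000)."""
        rng = np.random.default_rng(42)
        n = 10_000
        lam = -np.log(0.8) / 5.0  # exponential net survival, RS(5) = 0.8
        q = 0.02
        lt = flat_lifetable(q)
        cases = []
        for i in range(n):
            t_cancer = rng.exponential(1.0 / lam)
            j_cancer = max(int(np.ceil(t_cancer)), 1)
            j_bg = int(rng.geometric(q))
            j = min(j_cancer, j_bg)
            death = 2000 + j if 2000 + j <= TOY.obs_year_max else None
            cases.append(case(i, age=60, year=2000, death=death, cause="cancer"))
        tab = tabulate_pohar_perme(cases, lt, TOY)
        row = tab.data[(tab.data["interval"] == 5) & (tab.data["group_index"] == 1)]
        rs5, se5 = float(row["rs"].iloc[0]), float(row["se"].iloc[0])
        assert abs(rs5 - 0.8) < 2 * max(se5, 0.005)

    def test_empty_stratum_absent_not_zero(self):
        cases = [case(1, age=30, year=2000)]  # only the youngest group populated
        tab = tabulate_pohar_perme(cases, flat_lifetable(0.0), TOY)
        assert set(tab.data["group_index"].unique()) == {0}


@given(
    st.lists(
        st.tuples(
            st.integers(30, 80),       # age at diagnosis
            st.integers(1998, 2006),   # diagnosis year
            st.integers(0, 12),        # years to death; > follow-up means alive
        ),
        min_size=1,
        max_size=40,
    )
)
def test_pohar_perme_equals_actuarial_when_expected_mortality_zero(triples):
    """With a zero life table the estimator is the classic actuarial one."""
    cases = []
    for i, (age, year, dt) in enumerate(triples):
        death = year + dt if 0 < dt <= TOY.obs_year_max - year else None
        cases.append(case(i, age=age, year=year, death=death))
    tab = tabulate_pohar_perme(cases, flat_lifetable(0.0), TOY)
    for gi, (alo, ahi) in enumerate(TOY.survival_age_groups):
        for pi, (plo, phi) in enumerate(TOY.survival_periods):
            members = [c for c in cases if alo <= c.age_dx <= ahi and plo <= c.year_dx <= phi]
            if not members:
                continue
            oracle = classic_actuarial(members, TOY.obs_year_max - plo, TOY.obs_year_max)
            got = tab.stratum(gi, pi).sort_values("interval")["rs"].to_numpy()
            np.testing.assert_allclose(got, oracle[: got.size], atol=1e-12)


def cure_model_table(c_logit_ref, slope, lam, gam, config, se=0.01, noise_rng=None,
                     ref_year=None):
    """Tabulation generated exactly from the mixture cure law (+ optional noise)."""
    ref = ref_year if ref_year is not None else 0.5 * (config.obs_year_min + config.obs_year_max)
    rows = []
    for gi, _ in enumerate(config.survival_age_groups):
        for pi, (plo, phi) in enumerate(config.survival_periods):
            y_mid = 0.5 * (plo + phi)
            c = expit(c_logit_ref + slope * (y_mid - ref))
            for j in range(1, config.obs_year_max - plo + 1):
                rs = c + (1 - c) * np.exp(-((lam * j) ** gam))
                if noise_rng is not None:
                    rs += noise_rng.normal(0.0, se)
                rows.append(
                    {
                        "group_index": gi, "age_group": config.age_group_label(gi),
                        "period_index": pi, "period": f"{plo}-{phi}",
                        "year_mid": y_mid, "interval": j,
                        "rs": rs, "se": se, "n_at_risk": 1000.0,
                    }
                )
    return RelSurvTable(pd.DataFrame(rows))


class TestMixtureCure:
    def test_exact_model_recovery(self, config):
        """Noiseless data from c = 0.7, exponential S_u: c recovered to 0.005."""
        table = cure_model_table(np.log(0.7 / 0.3), 0.0, 0.5, 1.0, config)
        params = fit_mixture_cure(table, config)
        for gi in range(3):
            c_hat = float(params.cure_fraction(gi, 1990))
            assert abs(c_hat - 0.7) < 0.005
            assert abs(params.shape[gi] - 1.0) < 0.05

    def test_unity_survival_drives_cure_to_boundary(self, config):
        table = cure_model_table(50.0, 0.0, 0.5, 1.0, config)  # rs == 1 throughout
        params = fit_mixture_cure(table, config)
        assert all(params.boundary_flags)
        assert np.all(params.cure_fraction(0, 1990) > 0.999)

    def test_trend_slope_recovery_over_replicates(self, config):
        """Noisy tabulations from a logit-cure slope of 0.03/yr: the mean
        estimate over 50 replicates is within 3 standard errors of truth."""
        rng = np.random.default_rng(202)
        slopes = []
        for _ in range(50):
            table = cure_model_table(
                0.8, 0.03, 0.25, 1.1, config, se=0.01, noise_rng=rng
            )
            params = fit_mixture_cure(table, config)
            slopes.extend(params.cure_slope)
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - 0.03) < 3 * sem

    def test_single_period_is_fatal(self):
        cfg1 = AnalysisConfig(
            obs_year_min=2003, obs_year_max=2007, proj_year_max=2010,
            survival_periods=((2003, 2007),), subphase_reference_year=2005,
        )
        table = cure_model_table(0.8, 0.0, 0.3, 1.0, cfg1)
        with pytest.raises(ValueError, match="periods"):
            fit_mixture_cure(table, cfg1)


class TestSurvivalSurface:
    @pytest.fixture()
    def surf(self, analysis, config):
        return survival_surface(analysis.cure, config)

    def test_rs_at_zero_duration_is_one(self, surf):
        for g in range(3):
            assert surf(0.0, g, 1990) == pytest.approx(1.0)

    def test_backcast_is_frozen_at_window_start(self, surf, config):
        d = np.arange(0, 30, dtype=float)
        for g in range(3):
            np.testing.assert_array_equal(
                surf(d, g, 1950), surf(d, g, config.obs_year_min)
            )

    def test_forward_trend_is_monotone_for_positive_cure_slope(self, surf, analysis, config):
        years = np.arange(config.obs_year_max, config.proj_year_max + 1)
        for g in range(3):
            if analysis.cure.cure_slope[g] > 0:
                rs5 = np.array([float(surf(5.0, g, y)) for y in years])
                assert np.all(np.diff(rs5) >= 0)

    def test_nonincreasing_in_duration(self, surf):
        d = np.linspace(0, 40, 200)
        for g in range(3):
            rs = surf(d, g, 2000)
            assert np.all(np.diff(rs) <= 1e-12)

    def test_asymptote_is_cure_fraction(self, surf, analysis):
        """RS(d) -> c as d grows; at d = 60 the gap is < 1e-6 for gamma >= 1."""
        for g in range(3):
            if analysis.cure.shape[g] >= 1.0:
                gap = float(surf(60.0, g, 2000)) - float(surf.cure_fraction(g, 2000))
                assert abs(gap) < 1e-6

    def test_negative_duration_is_fatal(self, surf):
        with pytest.raises(ValueError, match="nonnegative"):
            surf(-1.0, 0, 2000)

    def test_late_periods_survive_better_on_improving_fixture(self, analysis, config):
        """Tabulated 5-year net survival rises from the earliest to the latest
        period (the generator improves survival over calendar time)."""
        d = analysis.relsurv.data
        for gi in range(3):
            early = d[(d["group_index"] == gi) & (d["period_index"] == 0) & (d["interval"] == 5)]
            late = d[(d["group_index"] == gi) & (d["period_index"] == 3) & (d["interval"] == 5)]
            assert float(late["rs"].iloc[0]) > float(early["rs"].iloc[0])

    def test_cure_params_json_round_trip(self, tmp_path, analysis):
        p = tmp_path / "cure.json"
        analysis.cure.to_json(p)
        back = CureParams.from_json(p)
        np.testing.assert_allclose(back.cure_intercept, analysis.cure.cure_intercept)
        np.testing.assert_allclose(back.shape, analysis.cure.shape)
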