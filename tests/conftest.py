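"""Shared fixtures: one full-scale synthetic registry and its fitted pipeline.

The expensive objects (a ~90k-case simulated registry and the fitted
incidence/survival/prevalence chain) are built once per session; unit tests
use small hand-built inputs instead.
"""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from prevmod.apc_incidence import (
    RateSurface,
    fit_candidate_models,
    model_selection_table,
    project_incidence,
    tabulate_incidence,
)
from prevmod.net_survival import fit_mixture_cure, survival_surface, tabulate_pohar_perme
from prevmod.phase_of_care import apply_subphase, decompose_phases, estimate_event_proportions
from prevmod.prevalence_engine import compute_expected_mortality, compute_prevalence
from prevmod.registry_model import AnalysisConfig, LifeTable, filter_eligible
from prevmod.synthetic_registry import SimulationParams, simulate_registry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_config():
    """A reduced observation window for cheap end-to-end runs."""
    return AnalysisConfig(
        obs_year_min=1988,
        obs_year_max=2007,
        proj_year_max=2012,
        survival_periods=((1988, 1997), (1998, 2007)),
        subphase_reference_year=2005,
    )


@pytest.fixture(scope="session")
def sim(config):
    """Default full-scale synthetic registry (~90k registry cases)."""
    return simulate_registry(SimulationParams(), config)


@pytest.fixture(scope="session")
def analysis(sim, config):
    """The fitted chain on the default registry: rates, survival, prevalence."""
    eligible = filter_eligible(sim.cases, config)
    inc = tabulate_incidence(eligible, sim.population, config)
    fits = fit_candidate_models(inc)
    ranking = model_selection_table(fits)
    fit = next(f for f in fits if f.spec.label == "APC303")
    rates = RateSurface(
        project_incidence(
            fit, range(config.backcast_year_min, config.proj_year_max + 1), config
        )
    )
    relsurv = tabulate_pohar_perme(eligible, sim.lifetable, config)
    cure = fit_mixture_cure(relsurv, config)
    rs = survival_surface(cure, config)
    years = np.arange(config.obs_year_min, config.proj_year_max + 1)
    surface = compute_prevalence(rates, rs, sim.lifetable, sim.population, config, years)
    deaths = compute_expected_mortality(
        rates, rs, sim.lifetable, sim.population, config, years
    )
    phases = decompose_phases(surface, deaths, config, years)
    props = estimate_event_proportions(eligible, config)
    phases = apply_subphase(
        phases, props, range(config.obs_year_max + 1, config.proj_year_max + 1)
    )
    return SimpleNamespace(
        eligible=eligible,
        incidence=inc,
        fits=fits,
        ranking=ranking,
        fit=fit,
        rates=rates,
        relsurv=relsurv,
        cure=cure,
        rs=rs,
        years=years,
        surface=surface,
        deaths=deaths,
        phases=phases,
        props=props,
    )


@pytest.fixture()
def zero_lifetable(config):
    """A life table with no expected mortality over a generous grid."""
    ages = np.arange(0, 106)
    years = np.arange(config.backcast_year_min, config.proj_year_max + 1)
    return LifeTable(np.zeros((ages.size, years.size)), ages, years)
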