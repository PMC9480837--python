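"""Shared fixtures: hand-built toy models and a seeded synthetic panel."""

import logging

import cobra
import pytest
from cobra import Metabolite, Reaction

from vitaprof import (
    AssessmentConfig,
    compute_minimal_medium,
    default_family_table,
    enumerate_formulations,
    pool_udm,
    remove_families,
    rich_medium,
)
from vitaprof.synth import generate_panel

logging.getLogger("vitaprof").setLevel(logging.ERROR)
logging.getLogger("cobra").setLevel(logging.ERROR)


def build_chain_model() -> cobra.Model:
    """EX_A (lb -10) -> transport -> biomass, all coefficients 1."""
    model = cobra.Model("chain")
    a_e = Metabolite("A_e", compartment="e")
    a_c = Metabolite("A_c", compartment="c")
    ex = Reaction("EX_A_e", lower_bound=-10, upper_bound=1000)
    ex.add_metabolites({a_e: -1})
    transport = Reaction("T_A", lower_bound=0, upper_bound=1000)
    transport.add_metabolites({a_e: -1, a_c: 1})
    biomass = Reaction("biomass", lower_bound=0, upper_bound=1000)
    biomass.add_metabolites({a_c: -1})
    model.add_reactions([ex, transport, biomass])
    model.objective = "biomass"
    return model


def build_branched_model() -> cobra.Model:
    """Two substrate routes into biomass with capacities 3 and 4."""
    model = cobra.Model("branched")
    mets = {
        name: Metabolite(name, compartment="e" if name.endswith("_e") else "c")
        for name in ("A_e", "B_e", "X_c")
    }
    ex_a = Reaction("EX_A_e", lower_bound=-3, upper_bound=1000)
    ex_a.add_metabolites({mets["A_e"]: -1})
    ex_b = Reaction("EX_B_e", lower_bound=-4, upper_bound=1000)
    ex_b.add_metabolites({mets["B_e"]: -1})
    route_a = Reaction("R_A", lower_bound=0, upper_bound=1000)
    route_a.add_metabolites({mets["A_e"]: -1, mets["X_c"]: 1})
    route_b = Reaction("R_B", lower_bound=0, upper_bound=1000)
    route_b.add_metabolites({mets["B_e"]: -1, mets["X_c"]: 1})
    biomass = Reaction("biomass", lower_bound=0, upper_bound=1000)
    biomass.add_metabolites({mets["X_c"]: -1})
    model.add_reactions([ex_a, ex_b, route_a, route_b, biomass])
    model.objective = "biomass"
    return model


@pytest.fixture
def chain_model():
    return build_chain_model()


@pytest.fixture
def branched_model():
    return build_branched_model()


@pytest.fixture(scope="session")
def families():
    return default_family_table()


@pytest.fixture(scope="session")
def config():
    return AssessmentConfig()


@pytest.fixture(scope="session")
def panel(families):
    """Seeded 10-strain panel with its pooled media and formulations."""
    models, truth, specs = generate_panel(10, 0.2, seed=3, families=families)
    minimal_media = [
        compute_minimal_medium(m, rich_medium(m), 0.8) for m in models
    ]
    udm = pool_udm(minimal_media)
    vfm = remove_families(udm, families)
    formulations = enumerate_formulations(vfm, families, udm)
    return {
        "models": models,
        "truth": truth,
        "specs": specs,
        "minimal_media": minimal_media,
        "udm": udm,
        "vfm": vfm,
        "formulations": formulations,
    }
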