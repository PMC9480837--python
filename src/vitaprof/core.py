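"""Model I/O, medium handling and flux balance analysis.

Genome-scale models are held as :class:`cobra.Model` objects; cobrapy (with
the GLPK backend through optlang) provides the stoichiometric container, the
SBML Level-3 FBC and JSON readers/writers, and the LP machinery.  This module
wraps them behind the small surface the rest of the package uses: reading and
writing models, applying a growth medium to exchange bounds, solving FBA
(optionally parsimonious), and inspecting metabolite turnover in a solution.

Conventions
-----------
* Exchange reactions carry a single extracellular metabolite with coefficient
  -1; positive flux is secretion, negative flux is uptake.
* A :data:`Medium` maps exchange-reaction ids to strictly positive maximum
  uptake rates (mmol/gDW/h).  ``apply_medium`` negates the rate into the
  exchange lower bound and closes every exchange the medium does not list.
* Growth is the biomass objective value in gDW/h; values below
  ``FLUX_TOLERANCE`` are reported as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
from cobra.flux_analysis import pfba
from cobra.io import load_json_model, read_sbml_model, save_json_model, write_sbml_model

from .errors import ContractError, ModelValidityError, SolverStatusError

logger = logging.getLogger(__name__)

#: Flux magnitudes below this are treated as zero (mmol/gDW/h; also used for
#: growth comparisons, gDW/h).
FLUX_TOLERANCE = 1e-6

#: A medium maps exchange reaction id -> maximum uptake rate (> 0).
Medium = dict[str, float]


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``status`` is ``"optimal"`` or ``"infeasible"``; on infeasibility the
    growth is 0 and the flux mapping is empty.
    """

    status: str
    growth: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a genome-scale model from SBML-FBC (``sbml_fbc``) or cobra-style
    JSON (``native_json``); the format is inferred from the suffix when not
    given.  Raises :class:`ModelValidityError` if the file has no biomass
    objective and propagates parser errors for malformed files.
    """
    path = Path(path)
    if format is None:
        format = "native_json" if path.suffix == ".json" else "sbml_fbc"
    if format == "native_json":
        model = load_json_model(str(path))
    elif format == "sbml_fbc":
        model = read_sbml_model(str(path))
    else:
        raise ContractError(f"unknown model format: {format!r}")
    validate_model(model)
    return model


def write_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    """Serialize a model to SBML-FBC or native JSON (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "native_json" if path.suffix == ".json" else "sbml_fbc"
    if format == "native_json":
        save_json_model(model, str(path), sort=True)
    elif format == "sbml_fbc":
        write_sbml_model(model, str(path))
    else:
        raise ContractError(f"unknown model format: {format!r}")


def biomass_reaction(model: cobra.Model) -> cobra.Reaction:
    """The single reaction carrying the (linear) biomass objective."""
    coeffs = cobra.util.solver.linear_reaction_coefficients(model)
    if len(coeffs) != 1:
        raise ModelValidityError(
            f"model {model.id!r} must have exactly one objective (biomass) "
            f"reaction, found {len(coeffs)}"
        )
    return next(iter(coeffs))


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants required downstream: a unique biomass
    objective and well-formed exchange reactions."""
    biomass_reaction(model)
    for rxn in model.exchanges:
        if len(rxn.metabolites) != 1:
            raise ModelValidityError(
                f"exchange {rxn.id} touches {len(rxn.metabolites)} metabolites"
            )


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def apply_medium(
    model: cobra.Model,
    medium: Mapping[str, float],
    missing: str = "warn",
) -> cobra.Model:
    """Impose a medium on the model's exchange bounds, in place.

    Every exchange listed in ``medium`` gets ``lower_bound = -rate``; every
    exchange *not* listed is closed to uptake (``lower_bound = 0``).
    Secretion (upper) bounds are untouched.  Keys naming reactions the model
    lacks are skipped with a warning by default (``missing="warn"``) or raise
    (``missing="error"``): a pooled community medium necessarily lists
    components some strains cannot transport.  A key naming a non-exchange
    reaction always raises :class:`ContractError`.

    Mutations are registered with cobrapy's history mechanism, so calling
    inside a ``with model:`` block makes them revert on exit.
    """
    if missing not in ("warn", "error", "ignore"):
        raise ContractError(f"missing must be 'warn', 'error' or 'ignore': {missing!r}")
    exchange_ids = {r.id for r in model.exchanges}
    for key, rate in medium.items():
        if rate <= 0:
            raise ContractError(f"medium rate for {key} must be > 0, got {rate}")
        if key in model.reactions and key not in exchange_ids:
            raise ContractError(f"medium key {key} names a non-exchange reaction")
    for rxn in model.exchanges:
        if rxn.id in medium:
            rxn.lower_bound = -abs(medium[rxn.id])
        else:
            rxn.lower_bound = 0.0
    absent = [k for k in medium if k not in exchange_ids]
    if absent:
        if missing == "error":
            raise ContractError(
                f"medium keys absent from model {model.id!r}: {sorted(absent)}"
            )
        if missing == "warn":
            logger.warning(
                "model %s lacks %d medium component(s): %s",
                model.id, len(absent), ", ".join(sorted(absent)[:5]),
            )
    return model


def read_medium_tsv(path: str | Path) -> Medium:
    """Read a two-column TSV (exchange_reaction_id, max_uptake_rate)."""
    medium: Medium = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, rate = line.split("\t")
            if key == "exchange_reaction_id":  # header
                continue
            medium[key] = float(rate)
    return medium


def write_medium_tsv(medium: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("exchange_reaction_id\tmax_uptake_rate\n")
        for key in sorted(medium):
            fh.write(f"{key}\t{medium[key]:.10g}\n")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def solve_fba(model: cobra.Model, parsimonious: bool = False) -> FluxSolution:
    """Maximize biomass flux under steady state and bounds.

    With ``parsimonious=True`` the returned fluxes additionally minimize the
    total absolute flux at the optimal growth (pFBA), which controls the
    degeneracy of alternate optima before flux inspection.
    """
    growth = model.slim_optimize()
    status = model.solver.status
    if status == "unbounded" or (growth is not None and math.isinf(growth)):
        raise SolverStatusError(
            f"unbounded biomass objective in model {model.id!r}", status=status
        )
    if growth is None or math.isnan(growth):
        if status not in ("infeasible", "optimal"):
            raise SolverStatusError(
                f"solver failed on model {model.id!r}", status=status
            )
        return FluxSolution(status="infeasible", growth=0.0)
    if parsimonious:
        solution = pfba(model)
    else:
        solution = model.optimize()
    growth = float(solution.fluxes[biomass_reaction(model).id])
    if abs(growth) < FLUX_TOLERANCE:
        growth = 0.0
    return FluxSolution(
        status="optimal", growth=growth, fluxes=solution.fluxes.to_dict()
    )


def metabolite_turnover(
    model: cobra.Model,
    solution: FluxSolution,
    metabolite_ids: Iterable[str],
) -> tuple[float, float]:
    """Total production and consumption (both >= 0, mmol/gDW/h) of the listed
    metabolites by the model's internal (non-exchange) reactions at the given
    solution.  The biomass pseudo-reaction counts as a consumer, matching the
    notion of a nutrient being "utilized" by growth.
    """
    if not solution.optimal:
        raise ContractError("turnover requires an optimal solution")
    met_ids = set(metabolite_ids)
    unknown = met_ids - {m.id for m in model.metabolites}
    if unknown:
        raise ContractError(f"unknown metabolite id(s): {sorted(unknown)}")
    exchange_ids = {r.id for r in model.exchanges}
    production = 0.0
    consumption = 0.0
    for met_id in met_ids:
        met = model.metabolites.get_by_id(met_id)
        for rxn in met.reactions:
            if rxn.id in exchange_ids:
                continue
            contribution = rxn.metabolites[met] * solution.fluxes.get(rxn.id, 0.0)
            if contribution > 0:
                production += contribution
            else:
                consumption -= contribution
    return production, consumption


def growth_on(model: cobra.Model, medium: Mapping[str, float]) -> float:
    """Growth rate on a medium, leaving the model's bounds untouched."""
    with model:
        apply_medium(model, medium, missing="ignore")
        growth = model.slim_optimize()
    if growth is None or math.isnan(growth):
        return 0.0
    return 0.0 if abs(growth) < FLUX_TOLERANCE else float(growth)
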