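"""Per-strain vitamin profiling: the two assessment branches plus export.

Branch 1 (requirements): grow the strain on every combinatorial formulation
(VFM plus each subset of vitamin families) and record a Boolean growth row.
Because adding nutrients can only relax the LP, rows are monotone in the
subset order, so the *essential* set is the intersection of the included
families over all growth-positive formulations; disjunctive ("B1 OR B2")
requirements surface as multiple minimal sufficient sets instead.

Branch 2 (capabilities): for each family, remove its members from the full
UDM (UDM-1) and ask whether the strain still grows above threshold while its
internal network both produces and consumes the family's active forms — the
synthesis-and-utilization test, evaluated on the parsimonious solution so
degenerate alternate optima do not flip the call.

The export variant additionally forces a small secretion flux through the
family's exchange and checks that growth survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import pandas as pd

from .core import Medium, apply_medium, metabolite_turnover, solve_fba
from .errors import ContractError, InternalConsistencyError
from .families import VitaminFamily, member_exchanges, member_intracellular
from .media import MediaFormulation, remove_families

logger = logging.getLogger(__name__)

ESSENTIAL = "essential"
OPTIONAL = "optional"
NON_NUTRIENT = "non_nutrient"


@dataclass(frozen=True)
class AssessmentConfig:
    """Thresholds of the screen.

    growth_threshold: minimum growth (gDW/h) counted as viable; 0.09
        corresponds to a six-to-eight-hour doubling time, the slowest growth
        compatible with persistence against gut transit.
    minimal_medium_target: growth (gDW/h) the per-strain minimal media must
        support (0.8, a proxy for optimal growth).
    flux_tolerance: fluxes below this are zero (mmol/gDW/h).
    export_epsilon: secretion flux forced in the export assessment.
    incremental_shortcut: mark supersets of known-sufficient family sets as
        growth-positive without solving (exact under LP monotonicity).
    """

    growth_threshold: float = 0.09
    minimal_medium_target: float = 0.8
    flux_tolerance: float = 1e-6
    export_epsilon: float = 0.001
    incremental_shortcut: bool = True

    def __post_init__(self):
        for name in ("growth_threshold", "minimal_medium_target",
                     "flux_tolerance", "export_epsilon"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if not self.growth_threshold < self.minimal_medium_target:
            raise ContractError("growth_threshold must be < minimal_medium_target")


@dataclass
class EssentialityResult:
    strain_id: str
    row: dict[str, int]                    # formulation label -> 0/1
    essential: frozenset[str]
    minimal_sufficient_sets: list[frozenset[str]]
    requires_beyond_panel: bool = False
    n_solves: int = 0


@dataclass
class StrainProfile:
    """Per-family essential/optional/non-nutrient status of one strain."""

    strain_id: str
    status: dict[str, str]
    minimal_sufficient_sets: list[frozenset[str]] = field(default_factory=list)

    @property
    def essential(self) -> frozenset[str]:
        return frozenset(f for f, s in self.status.items() if s == ESSENTIAL)

    @property
    def optional(self) -> frozenset[str]:
        return frozenset(f for f, s in self.status.items() if s == OPTIONAL)

    @property
    def n_essential(self) -> int:
        return len(self.essential)

    @property
    def n_optional(self) -> int:
        return len(self.optional)

    @property
    def is_prototroph(self) -> bool:
        return self.n_essential == 0


# ---------------------------------------------------------------------------
# branch 1: requirements
# ---------------------------------------------------------------------------

def _grows(model: cobra.Model, medium: Medium, config: AssessmentConfig) -> bool:
    with model:
        apply_medium(model, medium, missing="ignore")
        growth = model.slim_optimize(error_value=None)
    if growth is None:
        return False
    return growth >= config.growth_threshold - config.flux_tolerance


def assess_essential(
    model: cobra.Model,
    vfm: Mapping[str, float],
    formulations: Sequence[MediaFormulation],
    config: AssessmentConfig = AssessmentConfig(),
) -> EssentialityResult:
    """Evaluate the Boolean growth row over all combinatorial formulations.

    ``formulations`` must come from ``enumerate_formulations`` (ascending
    subset size, canonical labels, first element = VFM).  With the
    incremental shortcut on, a formulation whose family set contains a
    known-sufficient set is recorded as growth-positive without solving; the
    row equals the exhaustive one by monotonicity.

    If no formulation supports growth the strain requires nutrients beyond
    the assessed panel: the row is all-zero, ``requires_beyond_panel`` is set
    and the essential set degenerates to all assessed families (intersection
    over an empty collection).
    """
    if not formulations:
        raise ContractError("formulations must be non-empty")
    if formulations[0].included_families:
        raise ContractError("first formulation must be the VFM (empty subset)")
    all_families = frozenset().union(*(f.included_families for f in formulations))
    row: dict[str, int] = {}
    sufficient: list[frozenset[str]] = []   # minimal growth-positive sets
    positive: list[frozenset[str]] = []
    n_solves = 0
    for formulation in formulations:
        fams = formulation.included_families
        if config.incremental_shortcut and any(s <= fams for s in sufficient):
            cell = 1
        else:
            n_solves += 1
            cell = int(_grows(model, formulation.medium, config))
            if cell and not any(s <= fams for s in sufficient):
                sufficient.append(fams)
        row[formulation.label] = cell
        if cell:
            positive.append(fams)
    if not positive:
        return EssentialityResult(
            strain_id=model.id,
            row=row,
            essential=all_families,
            minimal_sufficient_sets=[],
            requires_beyond_panel=True,
            n_solves=n_solves,
        )
    essential = frozenset.intersection(*positive)
    # minimal elements of the positive sets (an antichain)
    minimal = [s for s in sufficient if not any(t < s for t in sufficient)]
    minimal.sort(key=lambda s: (len(s), sorted(s)))
    return EssentialityResult(
        strain_id=model.id,
        row=row,
        essential=essential,
        minimal_sufficient_sets=minimal,
        n_solves=n_solves,
    )


# ---------------------------------------------------------------------------
# branch 2: capabilities
# ---------------------------------------------------------------------------

def assess_synthesis(
    model: cobra.Model,
    udm: Mapping[str, float],
    family: VitaminFamily,
    config: AssessmentConfig = AssessmentConfig(),
) -> bool:
    """True iff on UDM minus this family the strain grows above threshold and
    its internal network both produces and consumes the family's active forms
    (parsimonious solution)."""
    medium = remove_families(udm, [family])
    with model:
        apply_medium(model, medium, missing="ignore")
        solution = solve_fba(model, parsimonious=True)
    if not solution.optimal:
        return False
    if solution.growth < config.growth_threshold - config.flux_tolerance:
        return False
    intracellular = member_intracellular(model, family)
    if not intracellular:
        return False
    production, consumption = metabolite_turnover(model, solution, intracellular)
    return (production >= config.flux_tolerance
            and consumption >= config.flux_tolerance)


def assess_export(
    model: cobra.Model,
    udm: Mapping[str, float],
    family: VitaminFamily,
    config: AssessmentConfig = AssessmentConfig(),
) -> bool:
    """True iff the strain still grows above threshold when constrained to
    secrete at least ``export_epsilon`` of a family member on UDM minus the
    family (secretion may be optional at the optimum, hence the forcing)."""
    medium = remove_families(udm, [family])
    exchange_ids = member_exchanges(model, family)
    if not exchange_ids:
        logger.info("model %s has no exchange for family %s", model.id, family.name)
        return False
    for ex_id in exchange_ids:
        with model:
            apply_medium(model, medium, missing="ignore")
            rxn = model.reactions.get_by_id(ex_id)
            if rxn.upper_bound < config.export_epsilon:
                continue
            rxn.lower_bound = config.export_epsilon
            growth = model.slim_optimize(error_value=None)
        if growth is not None and growth >= config.growth_threshold - config.flux_tolerance:
            return True
    return False


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def build_profile(
    strain_id: str,
    essential: Iterable[str],
    synthesized: Mapping[str, bool],
    families: Sequence[VitaminFamily],
    minimal_sufficient_sets: Sequence[frozenset[str]] = (),
) -> StrainProfile:
    """Combine the two branches into one per-family status partition:
    essential beats everything, synthesized-and-not-essential is optional,
    the rest are non-nutrients.  A family reported both essential and
    synthesized contradicts the screen's consistency guarantee and raises
    :class:`InternalConsistencyError`."""
    names = [f.name for f in families]
    essential = frozenset(essential)
    unknown = essential - set(names) | set(synthesized) - set(names)
    if unknown:
        raise ContractError(f"unknown family name(s): {sorted(unknown)}")
    clash = {f for f in essential if synthesized.get(f, False)}
    if clash:
        raise InternalConsistencyError(
            f"strain {strain_id}: families both essential and synthesized: {sorted(clash)}"
        )
    status = {}
    for name in names:
        if name in essential:
            status[name] = ESSENTIAL
        elif synthesized.get(name, False):
            status[name] = OPTIONAL
        else:
            status[name] = NON_NUTRIENT
    return StrainProfile(
        strain_id=strain_id,
        status=status,
        minimal_sufficient_sets=list(minimal_sufficient_sets),
    )


def profile_strain(
    model: cobra.Model,
    udm: Mapping[str, float],
    vfm: Mapping[str, float],
    formulations: Sequence[MediaFormulation],
    families: Sequence[VitaminFamily],
    config: AssessmentConfig = AssessmentConfig(),
) -> tuple[StrainProfile, EssentialityResult, dict[str, bool], dict[str, bool]]:
    """Run both branches and the export variant for one strain; returns the
    profile, the essentiality result, and per-family synthesis/export flags."""
    result = assess_essential(model, vfm, formulations, config)
    synthesized = {f.name: assess_synthesis(model, udm, f, config) for f in families}
    exports = {
        f.name: (synthesized[f.name] and assess_export(model, udm, f, config))
        for f in families
    }
    profile = build_profile(
        model.id, result.essential, synthesized, families,
        result.minimal_sufficient_sets,
    )
    return profile, result, synthesized, exports


# ---------------------------------------------------------------------------
# tables and concordance
# ---------------------------------------------------------------------------

def boolean_table(results: Sequence[EssentialityResult]) -> pd.DataFrame:
    """Stack essentiality rows into the Boolean growth table (strains as
    rows, canonical formulation labels as columns)."""
    if not results:
        raise ContractError("no results to tabulate")
    frame = pd.DataFrame(
        [r.row for r in results], index=[r.strain_id for r in results]
    )
    frame.index.name = "strain"
    return frame


def profiles_table(profiles: Sequence[StrainProfile]) -> pd.DataFrame:
    """Long-format (strain, family, status) table."""
    rows = [
        {"strain": p.strain_id, "family": fam, "status": st}
        for p in profiles
        for fam, st in p.status.items()
    ]
    return pd.DataFrame(rows, columns=["strain", "family", "status"])


def od_concordance(
    profiles: Mapping[str, StrainProfile],
    od_table: pd.DataFrame,
    high: float = 80.0,
    low: float = 20.0,
) -> tuple[pd.DataFrame, float]:
    """Compare predicted requirements with in vitro vitamin-omission growth.

    ``od_table`` needs columns strain, family, pct_max_od: the optical
    density in the single-omission culture as a percentage of the maximum OD
    in complete medium.  Above ``high`` the strain did not need the vitamin,
    below ``low`` it did; in between is inconclusive and excluded from the
    match rate.
    """
    required = {"strain", "family", "pct_max_od"}
    if not required <= set(od_table.columns):
        raise ContractError(f"od_table needs columns {sorted(required)}")
    verdicts = []
    for record in od_table.itertuples(index=False):
        if record.strain not in profiles:
            raise ContractError(f"no profile for strain {record.strain!r}")
        profile = profiles[record.strain]
        if record.family not in profile.status:
            raise ContractError(
                f"family {record.family!r} not assessed for {record.strain!r}"
            )
        predicted_required = profile.status[record.family] == ESSENTIAL
        od = float(record.pct_max_od)
        if od > high:
            verdict = "mismatch" if predicted_required else "match"
        elif od < low:
            verdict = "match" if predicted_required else "mismatch"
        else:
            verdict = "inconclusive"
        verdicts.append(
            {
                "strain": record.strain,
                "family": record.family,
                "pct_max_od": od,
                "predicted_essential": predicted_required,
                "verdict": verdict,
            }
        )
    frame = pd.DataFrame(verdicts)
    conclusive = frame[frame.verdict != "inconclusive"]
    rate = (
        float((conclusive.verdict == "match").sum() / len(conclusive))
        if len(conclusive)
        else float("nan")
    )
    return frame, rate
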