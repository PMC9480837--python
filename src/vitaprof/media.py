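"""Defined-media design: minimal media, pooling, and combinatorial formulations.

The workflow mirrors how a universal defined medium (UDM) is built for a
strain panel: compute an anaerobic minimal medium per strain at a target
growth of 0.8 gDW/h, pool all minimal media into one rich UDM, strip the
assessed vitamin families to get the vitamin-free medium (VFM), and enumerate
every presence/absence combination of the families on top of the VFM
(2^n formulations, the combinatorial essentiality design).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
from cobra.medium import minimal_medium as _cobra_minimal_medium

from .core import FLUX_TOLERANCE, Medium, apply_medium, growth_on
from .errors import ContractError, InfeasibleMediumError
from .families import VitaminFamily, medium_keys_for_family

logger = logging.getLogger(__name__)

#: Uptake rate given to a family member exchange that never occurred in the
#: pooled UDM (mmol/gDW/h); matches the rich-medium rate of the synthetic world.
DEFAULT_MEMBER_RATE = 10.0


@dataclass(frozen=True)
class MediaFormulation:
    """One combinatorial medium: VFM plus a subset of vitamin families."""

    label: str
    medium: Medium = field(hash=False)
    included_families: frozenset[str] = frozenset()


def formulation_label(included: Iterable[str]) -> str:
    """Canonical label: '+'-joined sorted family names, empty set -> 'VFM'."""
    names = sorted(included)
    return "+".join(names) if names else "VFM"


# ---------------------------------------------------------------------------
# minimal media
# ---------------------------------------------------------------------------

def compute_minimal_medium(
    model: cobra.Model,
    candidate_medium: Mapping[str, float],
    target_growth: float = 0.8,
    exact: bool = False,
) -> Medium:
    """Irreducible sub-medium of ``candidate_medium`` supporting
    ``target_growth``.

    Fixes growth at the target and minimizes total import flux (cobrapy's
    ``minimal_medium``), then greedily prunes retained components in
    lexicographic id order; the result is irreducible — dropping any single
    retained component pushes growth below the target.  ``exact=True``
    switches to the MILP that minimizes the *number* of components instead of
    total flux (slower; needs a MILP-capable solver such as GLPK).

    Raises :class:`InfeasibleMediumError` if the model cannot reach the
    target even on the full candidate medium.
    """
    with model:
        apply_medium(model, candidate_medium, missing="ignore")
        growth = model.slim_optimize()
        if growth is None or not growth >= target_growth - FLUX_TOLERANCE:
            raise InfeasibleMediumError(
                f"strain {model.id!r} cannot reach growth {target_growth} on the "
                f"candidate medium (got {growth})",
                strain_id=model.id,
            )
        series = _cobra_minimal_medium(
            model, target_growth, minimize_components=exact
        )
    if series is None:
        raise InfeasibleMediumError(
            f"minimal medium computation failed for strain {model.id!r}",
            strain_id=model.id,
        )
    medium: Medium = {
        key: float(rate)
        for key, rate in series.items()
        if key in candidate_medium and rate > FLUX_TOLERANCE
    }
    # greedy pruning, deterministic lexicographic order
    for key in sorted(medium):
        trial = {k: v for k, v in medium.items() if k != key}
        if growth_on(model, trial) >= target_growth - FLUX_TOLERANCE:
            medium = trial
    return medium


def pool_udm(minimal_media: Sequence[Mapping[str, float]]) -> Medium:
    """Pool per-strain minimal media into one universal defined medium: the
    union of components, each at the maximum rate seen across strains (so
    every strain's own minimal medium is dominated by the pool)."""
    if not minimal_media:
        raise ContractError("cannot pool an empty collection of media")
    pooled: Medium = {}
    for medium in minimal_media:
        for key, rate in medium.items():
            pooled[key] = max(pooled.get(key, 0.0), float(rate))
    return pooled


def annotate_components(
    medium: Mapping[str, float], category_map: Mapping[str, str]
) -> "pd.DataFrame":
    """Tabulate a medium with nutrient-category annotations (simple sugars,
    amino acids, ..., main vitamins); unmapped components get 'other'."""
    import pandas as pd

    rows = [
        {
            "component": key,
            "max_uptake_rate": medium[key],
            "category": category_map.get(key, "other"),
        }
        for key in sorted(medium)
    ]
    return pd.DataFrame(rows, columns=["component", "max_uptake_rate", "category"])


# ---------------------------------------------------------------------------
# family removal and combinatorial design
# ---------------------------------------------------------------------------

def remove_families(
    medium: Mapping[str, float],
    families: Iterable[VitaminFamily],
) -> Medium:
    """Drop every exchange whose compound is a *member* (active form or
    analogue) of any listed family; precursor components are retained so de
    novo biosynthesis stays possible."""
    drop: set[str] = set()
    for family in families:
        drop.update(medium_keys_for_family(medium, family))
    return {k: float(v) for k, v in medium.items() if k not in drop}


def enumerate_formulations(
    vfm: Mapping[str, float],
    families: Sequence[VitaminFamily],
    udm_rates: Mapping[str, float],
    default_member_rate: float = DEFAULT_MEMBER_RATE,
) -> list[MediaFormulation]:
    """All 2^n media from VFM plus every subset of the families, each member
    exchange at its UDM rate (or ``default_member_rate`` when the pooled UDM
    never contained it).  Sorted by ascending subset size, ties broken
    lexicographically by canonical label.
    """
    if not families:
        raise ContractError("families must be non-empty")
    if len(families) > 16:
        raise ContractError(
            f"{len(families)} families would enumerate {2 ** len(families)} media; "
            "refusing above 16"
        )
    names = [f.name for f in families]
    if len(set(names)) != len(names):
        raise ContractError("duplicate family names")
    member_rates: dict[str, Medium] = {}
    for family in families:
        keys = medium_keys_for_family(udm_rates, family)
        if keys:
            member_rates[family.name] = {k: float(udm_rates[k]) for k in keys}
        else:
            member_rates[family.name] = {
                f"EX_{m}_e": default_member_rate for m in sorted(family.members)
            }
    formulations = []
    for size in range(len(families) + 1):
        for combo in itertools.combinations(sorted(names), size):
            medium: Medium = dict(vfm)
            for name in combo:
                medium.update(member_rates[name])
            formulations.append(
                MediaFormulation(
                    label=formulation_label(combo),
                    medium=medium,
                    included_families=frozenset(combo),
                )
            )
    formulations.sort(key=lambda f: (len(f.included_families), f.label))
    return formulations


def experiment_plan(n_strains: int, n_families: int) -> dict[str, int]:
    """Size of the screening design: combinatorial formulations per strain,
    total combinatorial monocultures, and single-omission monocultures."""
    if n_strains < 0 or n_families < 0:
        raise ContractError("counts must be non-negative")
    n_formulations = 2 ** n_families
    return {
        "n_formulations": n_formulations,
        "combinatorial_monocultures": n_strains * n_formulations,
        "single_omission_monocultures": n_strains * n_families,
    }
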