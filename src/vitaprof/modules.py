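"""Interaction-module analysis: complementarity networks, functional
redundancy, and the random-group null model.

An interaction module (IM) is a pre-defined co-abundance/co-occurrence group
of gut species.  Given strain-level vitamin profiles, each module version is
summarized by

* the functional redundancy score fr = vs / (nv * nm), where vs is the total
  number of synthesized (optional) vitamin entries over the members, nv the
  number of assessed vitamins in the denominator, and nm the member count;
* the percentage of prototrophic members; and
* whether the module's vitamin complementarity network is complete, i.e.
  every member's required vitamin has at least one in-module provider.

The null model draws many random groups of strains and summarizes them the
same way; modules falling outside the dense random region of the
(fr, prototroph %) plane are candidate complementarity-driven (low fr, no
prototrophs) or exchange-independent (high fr, many prototrophs) units.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContractError
from .profiling import ESSENTIAL, OPTIONAL, StrainProfile

RANDOM_LIKE = "random_like"
COMPLEMENTARITY_DRIVEN = "complementarity_driven"
EXCHANGE_INDEPENDENT = "exchange_independent"
UNCLASSIFIED = "unclassified"

#: Eligibility rules for a module: at least this many original members, and
#: at least this fraction of them matched to profiled strains.
MIN_MODULE_SIZE = 5
MIN_MAPPED_FRACTION = 0.5


@dataclass(frozen=True)
class RandomRegion:
    """The box in the (fr, prototroph %) plane where random groups cluster.
    Boundaries are closed on the random-like side."""

    fr_low: float = 0.3
    fr_high: float = 0.7
    prototroph_pct_low: float = 0.0
    prototroph_pct_high: float = 40.0


@dataclass
class InteractionModule:
    name: str
    original_size: int
    mapped: dict[str, list[str]]            # species -> candidate strain ids
    unmapped: list[str] = field(default_factory=list)

    @property
    def mapped_fraction(self) -> float:
        return len(self.mapped) / self.original_size if self.original_size else 0.0

    @property
    def eligible(self) -> bool:
        return (self.original_size >= MIN_MODULE_SIZE
                and self.mapped_fraction >= MIN_MAPPED_FRACTION)

    @property
    def versions(self) -> list[tuple[str, ...]]:
        """Every resolution of multi-candidate species to a single strain
        (cartesian product, species in sorted order)."""
        species = sorted(self.mapped)
        return [tuple(combo) for combo in
                itertools.product(*(self.mapped[s] for s in species))]


@dataclass
class ModuleSummary:
    name: str
    members: tuple[str, ...]
    vs: int
    nv: int
    nm: int
    fr_score: float
    prototroph_pct: float
    complete_complementarity: bool


@dataclass
class RandomGroupCloud:
    n_groups: int
    group_size: int
    seed: int
    summaries: list[ModuleSummary]
    random_region: RandomRegion = field(default_factory=RandomRegion)

    def prototroph_counts(self) -> np.ndarray:
        return np.array(
            [round(s.prototroph_pct * s.nm / 100.0) for s in self.summaries],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# species -> strain mapping
# ---------------------------------------------------------------------------

def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


def map_module_members(
    name: str,
    species_list: Sequence[str],
    strain_ids: Iterable[str],
    hints: Mapping[str, str] | None = None,
) -> InteractionModule:
    """Match species names against strain ids by genus+species token prefix.

    Species with several candidate strains yield multiple module versions.
    ``hints`` can pin a species to one strain id.  Unmatched species are
    recorded and lower the mapped fraction that gates eligibility.
    """
    strains = sorted(set(strain_ids))
    normalized = [(s, _normalize(s)) for s in strains]
    mapped: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for species in species_list:
        if hints and species in hints:
            mapped[species] = [hints[species]]
            continue
        token = _normalize(species)
        candidates = [s for s, norm in normalized
                      if norm == token or norm.startswith(token + "_")]
        if candidates:
            mapped[species] = candidates
        else:
            unmapped.append(species)
    return InteractionModule(
        name=name,
        original_size=len(species_list),
        mapped=mapped,
        unmapped=unmapped,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def complementarity_network(
    members: Sequence[str],
    profiles: Mapping[str, StrainProfile],
) -> nx.MultiDiGraph:
    """Directed provider -> requirer edges, one per (family, pair): a
    provider synthesizes (optional status) exactly a family the requirer
    needs (essential status).  No self-edges by construction since statuses
    partition families per strain."""
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(members)
    for requirer in members:
        for family in profiles[requirer].essential:
            for provider in members:
                if provider == requirer:
                    continue
                if family in profiles[provider].optional:
                    graph.add_edge(provider, requirer, family=family)
    return graph


def summarize_module(
    name: str,
    members: Sequence[str],
    profiles: Mapping[str, StrainProfile],
    nv: int | None = None,
) -> ModuleSummary:
    """Functional redundancy, prototroph percentage and complementarity
    completeness for one module version.

    ``nv`` is the denominator's number of assessed vitamins; it defaults to
    the number of families in the profiles but is exposed because reference
    analyses have used a different count than the assessed families.
    """
    if not members:
        raise ContractError("module has no members")
    missing = [m for m in members if m not in profiles]
    if missing:
        raise ContractError(f"no profile for module member(s): {missing}")
    families = sorted(profiles[members[0]].status)
    if nv is None:
        nv = len(families)
    if nv <= 0:
        raise ContractError("nv must be positive")
    nm = len(members)
    vs = sum(profiles[m].n_optional for m in members)
    prototrophs = sum(profiles[m].is_prototroph for m in members)
    complete = True
    for family in families:
        requirers = [m for m in members if profiles[m].status[family] == ESSENTIAL]
        providers = [m for m in members if profiles[m].status[family] == OPTIONAL]
        if requirers and not providers:
            complete = False
            break
    return ModuleSummary(
        name=name,
        members=tuple(members),
        vs=vs,
        nv=nv,
        nm=nm,
        fr_score=vs / (nv * nm),
        prototroph_pct=100.0 * prototrophs / nm,
        complete_complementarity=complete,
    )


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def sample_random_groups(
    profiles: Mapping[str, StrainProfile],
    n_groups: int,
    group_size: int,
    seed: int,
    nv: int | None = None,
    random_region: RandomRegion = RandomRegion(),
) -> RandomGroupCloud:
    """Draw ``n_groups`` groups of ``group_size`` strains uniformly without
    replacement within each group (strains may recur across groups) and
    summarize each; fully reproducible from ``seed``."""
    pool = sorted(profiles)
    if len(pool) < group_size:
        raise ContractError(
            f"pool of {len(pool)} strains is smaller than group_size={group_size}"
        )
    rng = np.random.default_rng(seed)
    summaries = []
    for i in range(n_groups):
        members = [pool[j] for j in rng.choice(len(pool), group_size, replace=False)]
        summaries.append(summarize_module(f"random{i:04d}", members, profiles, nv=nv))
    return RandomGroupCloud(
        n_groups=n_groups,
        group_size=group_size,
        seed=seed,
        summaries=summaries,
        random_region=random_region,
    )


def classify_region(
    summary: ModuleSummary, cloud: RandomGroupCloud
) -> str:
    """Place a module in the (fr, prototroph %) plane relative to the random
    cloud's region: inside the box (boundaries inclusive) is random-like;
    below it in fr with zero prototrophs is complementarity-driven; above it
    in both axes is exchange-independent; anything else is unclassified."""
    if not cloud.summaries:
        raise ContractError("empty random-group cloud")
    region = cloud.random_region
    fr, pct = summary.fr_score, summary.prototroph_pct
    if (region.fr_low <= fr <= region.fr_high
            and region.prototroph_pct_low <= pct <= region.prototroph_pct_high):
        return RANDOM_LIKE
    if fr < region.fr_low and pct == 0.0:
        return COMPLEMENTARITY_DRIVEN
    if fr > region.fr_high and pct > region.prototroph_pct_high:
        return EXCHANGE_INDEPENDENT
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def summaries_frame(summaries: Sequence[ModuleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": s.name,
                "nm": s.nm,
                "nv": s.nv,
                "vs": s.vs,
                "fr_score": s.fr_score,
                "prototroph_pct": s.prototroph_pct,
                "complete_complementarity": s.complete_complementarity,
            }
            for s in summaries
        ]
    )


def network_edge_list(graph: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [
        {"family": data["family"], "provider": u, "requirer": v}
        for u, v, data in graph.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=["family", "provider", "requirer"])
    return frame.sort_values(["family", "provider", "requirer"]).reset_index(drop=True)


def read_module_table(path) -> dict[str, list[str]]:
    """TSV with columns module, species (one row per member)."""
    modules: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("module\t"):
                continue
            module, species = line.split("\t")[:2]
            modules.setdefault(module, []).append(species)
    return modules
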