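"""Capability groups: clustering of requirement profiles and named groups.

Strains with similar essential-vitamin signatures cluster along an
auxotrophy-to-prototrophy spectrum.  Clustering is hierarchical agglomerative
on the Hamming distance between binary essential-status vectors; the named
groups themselves are user-supplied definitions (core required families plus
a tolerance band for extra requirements), because the reference grouping was
finalized by manual inspection and no algorithmic rule reproduces it exactly.

Group naming convention: a "+" after the core name admits one to three extra
required families beyond the core, "++" admits more than three, no suffix
means the core is the exact requirement set.  Prototrophs (no essential
families) always map to the dedicated "Prototrophs" group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import AmbiguousGroupError, ContractError
from .profiling import StrainProfile

PROTOTROPHS = "Prototrophs"
UNASSIGNED = "unassigned"

#: plus_level -> (min, max) count of extra required families beyond the core
PLUS_BANDS: dict[str, tuple[int, float]] = {
    "none": (0, 0),
    "plus": (1, 3),
    "double_plus": (4, float("inf")),
}


@dataclass(frozen=True)
class GroupDefinition:
    name: str
    core: frozenset[str]
    plus_level: str = "none"

    def __post_init__(self):
        if self.plus_level not in PLUS_BANDS:
            raise ContractError(f"unknown plus_level {self.plus_level!r}")

    def matches(self, essential: frozenset[str]) -> bool:
        if not self.core <= essential:
            return False
        lo, hi = PLUS_BANDS[self.plus_level]
        return lo <= len(essential - self.core) <= hi


def essential_matrix(
    profiles: Sequence[StrainProfile], families: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Binary strain x family matrix of essential status, rows sorted by
    strain id for deterministic downstream behaviour."""
    ordered = sorted(profiles, key=lambda p: p.strain_id)
    matrix = np.array(
        [[1 if f in p.essential else 0 for f in families] for p in ordered],
        dtype=float,
    )
    return matrix, [p.strain_id for p in ordered]


def cluster_profiles(
    profiles: Sequence[StrainProfile],
    families: Sequence[str],
    method: str = "average",
    cut: float | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Hierarchical agglomerative clustering of essential-status vectors.

    Returns the scipy linkage matrix, the strain order (sorted by id, which
    fixes tie-breaking), and — when ``cut`` is given — flat cluster labels at
    that cophenetic distance.
    """
    if len(profiles) < 2:
        raise ContractError("clustering needs at least two profiles")
    if method not in ("average", "complete"):
        raise ContractError(f"unsupported linkage {method!r}")
    matrix, order = essential_matrix(profiles, families)
    distances = pdist(matrix, metric="hamming")
    tree = linkage(distances, method=method)
    labels = fcluster(tree, t=cut, criterion="distance") if cut is not None else None
    return tree, order, labels


def assign_groups(
    profiles: Iterable[StrainProfile],
    definitions: Sequence[GroupDefinition],
) -> dict[str, str]:
    """Map each strain to the unique matching group, "Prototrophs" for
    strains without essential families, or "unassigned".  A strain matching
    two definitions raises :class:`AmbiguousGroupError` naming the conflict.
    """
    names = [d.name for d in definitions]
    if len(set(names)) != len(names):
        raise ContractError("duplicate group names in definitions")
    assignment: dict[str, str] = {}
    for profile in profiles:
        if profile.is_prototroph:
            assignment[profile.strain_id] = PROTOTROPHS
            continue
        hits = [d.name for d in definitions
                if d.name != PROTOTROPHS and d.matches(profile.essential)]
        if len(hits) > 1:
            raise AmbiguousGroupError(
                f"strain {profile.strain_id} (essential="
                f"{sorted(profile.essential)}) matches groups {hits}"
            )
        assignment[profile.strain_id] = hits[0] if hits else UNASSIGNED
    return assignment


def template_group_definitions() -> list[GroupDefinition]:
    """Eleven-group starting template spanning the prototrophy-to-auxotrophy
    spectrum, built from the naming rules alone (core requirement set, with
    "+" admitting 1-3 extra requirements and "++" more than three).

    The template encodes only the naming convention, not a validated
    partition of any particular strain collection: cores of different groups
    can both be subsets of one strain's essential set, in which case
    ``assign_groups`` raises its ambiguity error and the definitions must be
    tailored to the panel at hand.
    """
    return [
        GroupDefinition(PROTOTROPHS, frozenset(), "none"),
        GroupDefinition("K+", frozenset({"K"}), "plus"),
        GroupDefinition("B1", frozenset({"B1"}), "none"),
        GroupDefinition("B1+", frozenset({"B1"}), "plus"),
        GroupDefinition("B2+", frozenset({"B2"}), "plus"),
        GroupDefinition("B5+", frozenset({"B5"}), "plus"),
        GroupDefinition("B6+", frozenset({"B6"}), "plus"),
        GroupDefinition("B2++", frozenset({"B2"}), "double_plus"),
        GroupDefinition("B6++", frozenset({"B6"}), "double_plus"),
        GroupDefinition("B1B2K+", frozenset({"B1", "B2", "K"}), "plus"),
        GroupDefinition("B1B2K++", frozenset({"B1", "B2", "K"}), "double_plus"),
    ]


def read_group_definitions(path: str | Path) -> list[GroupDefinition]:
    """TSV with columns name, core (comma-joined families), plus_level."""
    definitions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, core, plus_level = line.split("\t")
            definitions.append(
                GroupDefinition(
                    name=name,
                    core=frozenset(t for t in core.split(",") if t),
                    plus_level=plus_level or "none",
                )
            )
    return definitions


def write_assignment_tsv(assignment: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tgroup\n")
        for strain in sorted(assignment):
            fh.write(f"{strain}\t{assignment[strain]}\n")
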