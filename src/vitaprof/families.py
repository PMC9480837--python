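"""Vitamin family definitions and id-matching helpers.

A *family* groups the biologically active forms and analogues of one vitamin
(e.g. thiamine, thiamine monophosphate and thiamine pyrophosphate for B1)
together with the media *precursors* from which the active forms can be made
de novo (e.g. thiazole for B1).  Removing a family from a medium removes the
member exchanges only — precursors stay, so a strain with an intact pathway
can still synthesize the active form.

Members and precursors are stored as compound tokens.  A medium key or
metabolite id matches a token either literally or via the widespread
``EX_<token>_<compartment>`` / ``<token>_<compartment>`` naming convention,
so family tables can list bare compound ids without enumerating every
compartment-suffixed variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import cobra

from .errors import ContractError

#: The eight assessed cofactor families: B vitamins plus the quinones
#: (menaquinones and ubiquinone-8, abbreviated K).
FAMILY_NAMES = ("B1", "B2", "B3", "B5", "B6", "B9", "B12", "K")


@dataclass(frozen=True)
class VitaminFamily:
    """Named group of active-form/analogue compound ids plus media precursors."""

    name: str
    members: frozenset[str]
    precursors: frozenset[str] = frozenset()

    def __post_init__(self):
        overlap = self.members & self.precursors
        if overlap:
            raise ContractError(
                f"family {self.name}: members and precursors overlap: {sorted(overlap)}"
            )


def default_family_table() -> list[VitaminFamily]:
    """Family table for the synthetic-model world: one active form
    (``vit<F>``) and one precursor (``pre<F>``) per family."""
    return [
        VitaminFamily(name, frozenset({f"vit{name}"}), frozenset({f"pre{name}"}))
        for name in FAMILY_NAMES
    ]


def read_family_table(path: str | Path) -> list[VitaminFamily]:
    """Read a TSV with columns family, members (comma-joined), precursors."""
    families: list[VitaminFamily] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            parts = line.split("\t")
            name = parts[0]
            members = frozenset(t for t in parts[1].split(",") if t)
            precursors = frozenset(
                t for t in (parts[2].split(",") if len(parts) > 2 else []) if t
            )
            if name in seen:
                raise ContractError(f"duplicate family name {name!r} in table")
            seen.add(name)
            families.append(VitaminFamily(name, members, precursors))
    return families


def write_family_table(families: Iterable[VitaminFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmembers\tprecursors\n")
        for fam in families:
            fh.write(
                f"{fam.name}\t{','.join(sorted(fam.members))}\t"
                f"{','.join(sorted(fam.precursors))}\n"
            )


# ---------------------------------------------------------------------------
# id matching
# ---------------------------------------------------------------------------

def compound_token(identifier: str) -> str:
    """Strip an ``EX_`` prefix and a trailing ``_<compartment>`` suffix."""
    token = identifier
    if token.startswith("EX_"):
        token = token[3:]
    if len(token) > 2 and token[-2] == "_":
        token = token[:-2]
    return token


def _matches(identifier: str, tokens: frozenset[str]) -> bool:
    return identifier in tokens or compound_token(identifier) in tokens


def medium_keys_for_family(
    medium: Mapping[str, float], family: VitaminFamily
) -> list[str]:
    """Medium keys whose exchanged compound is a *member* of the family."""
    return sorted(k for k in medium if _matches(k, family.members))


def member_exchanges(model: cobra.Model, family: VitaminFamily) -> list[str]:
    """Exchange reaction ids whose metabolite is a member of the family."""
    out = []
    for rxn in model.exchanges:
        met = next(iter(rxn.metabolites))
        if _matches(met.id, family.members) or _matches(rxn.id, family.members):
            out.append(rxn.id)
    return sorted(out)


def member_intracellular(model: cobra.Model, family: VitaminFamily) -> list[str]:
    """Intracellular metabolite ids that are members of the family."""
    out = []
    for met in model.metabolites:
        if met.compartment in ("e", "extracellular"):
            continue
        if _matches(met.id, family.members):
            out.append(met.id)
    return sorted(out)
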