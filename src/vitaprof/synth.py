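"""Synthetic toy genome-scale models with known vitamin phenotypes.

Every pipeline stage is testable without external model collections: this
module builds small anaerobic strains around a single carbon/energy substrate
with, per vitamin family, one of three phenotypes —

* ``auxotroph``: the active form is in the biomass reaction and importable
  (exchange + inward transporter) but there is no biosynthetic pathway, so
  the family is *essential*;
* ``synthesizer``: the active form is in biomass and made through a two-step
  pathway from an importable precursor (precursor import -> intermediate ->
  active form), so the family is *optional* — the two-step chain is the
  smallest structure that separates "the medium holds the precursor" from
  "the genome holds the pathway";
* ``indifferent``: no reaction touches the family, so it is a *non-nutrient*.

Synthesizers can additionally be *exporters*: an outward transporter plus a
secretion exchange with surplus pathway capacity.  Capping the pathway at
exactly the biomass-implied flux makes forced export infeasible, giving the
negative control for the export assessment.

No oxygen exchange is generated; the strains are anaerobic like the gut
communities they stand in for.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import cobra
import numpy as np
import pandas as pd
from cobra import Metabolite, Reaction

from .core import Medium, write_model
from .errors import ContractError
from .families import VitaminFamily, default_family_table
from .profiling import ESSENTIAL, NON_NUTRIENT, OPTIONAL

SYNTHESIZER = "synthesizer"
AUXOTROPH = "auxotroph"
INDIFFERENT = "indifferent"
PHENOTYPES = (SYNTHESIZER, AUXOTROPH, INDIFFERENT)

#: mmol of active vitamin consumed per gDW of biomass
VITAMIN_COEFF = 0.01
#: rich-medium uptake rate for every component (mmol/gDW/h)
RICH_RATE = 10.0
#: default (surplus) capacity of pathway and transport steps
WIDE_BOUND = 1000.0


@dataclass(frozen=True)
class StrainSpec:
    """Declarative recipe for one toy strain."""

    strain_id: str
    phenotypes: dict[str, str]            # family name -> phenotype
    exporters: frozenset[str] = frozenset()
    pathway_capacity: dict[str, float] = field(default_factory=dict)
    substrate_rate: float = RICH_RATE

    def __post_init__(self):
        bad = {f: p for f, p in self.phenotypes.items() if p not in PHENOTYPES}
        if bad:
            raise ContractError(f"unknown phenotype(s): {bad}")
        synthesizers = {f for f, p in self.phenotypes.items() if p == SYNTHESIZER}
        if not self.exporters <= synthesizers:
            raise ContractError(
                f"exporters must be synthesizers: {sorted(self.exporters - synthesizers)}"
            )


def _family_by_name(families: Sequence[VitaminFamily]) -> dict[str, VitaminFamily]:
    return {f.name: f for f in families}


def generate_strain_model(
    spec: StrainSpec,
    families: Sequence[VitaminFamily] | None = None,
) -> tuple[cobra.Model, pd.DataFrame]:
    """Build the cobra model for a spec plus its ground-truth rows
    (columns: strain, family, status, exports, vitamin_in_minimal_medium)."""
    if families is None:
        families = default_family_table()
    table = _family_by_name(families)
    unknown = set(spec.phenotypes) - set(table)
    if unknown:
        raise ContractError(f"spec names unknown families: {sorted(unknown)}")

    model = cobra.Model(spec.strain_id)
    sub_e = Metabolite("sub_e", name="substrate", compartment="e")
    sub_c = Metabolite("sub_c", name="substrate", compartment="c")
    ex_sub = Reaction("EX_sub_e", lower_bound=-spec.substrate_rate, upper_bound=WIDE_BOUND)
    ex_sub.add_metabolites({sub_e: -1})
    t_sub = Reaction("T_sub", lower_bound=0, upper_bound=WIDE_BOUND)
    t_sub.add_metabolites({sub_e: -1, sub_c: 1})
    biomass = Reaction("biomass", lower_bound=0, upper_bound=WIDE_BOUND)
    biomass.add_metabolites({sub_c: -1})
    reactions = [ex_sub, t_sub, biomass]

    for name in sorted(spec.phenotypes):
        phenotype = spec.phenotypes[name]
        if phenotype == INDIFFERENT:
            continue
        family = table[name]
        member = sorted(family.members)[0]
        vit_c = Metabolite(f"{member}_c", name=f"{name} active form", compartment="c")
        biomass.add_metabolites({vit_c: -VITAMIN_COEFF})
        if phenotype == AUXOTROPH:
            vit_e = Metabolite(f"{member}_e", name=f"{name} active form", compartment="e")
            ex = Reaction(f"EX_{member}_e", lower_bound=0, upper_bound=WIDE_BOUND)
            ex.add_metabolites({vit_e: -1})
            t_in = Reaction(f"T_{member}", lower_bound=0, upper_bound=WIDE_BOUND)
            t_in.add_metabolites({vit_e: -1, vit_c: 1})
            reactions += [ex, t_in]
        else:  # synthesizer: precursor import + two-step pathway
            precursor = sorted(family.precursors)[0]
            cap = spec.pathway_capacity.get(name, WIDE_BOUND)
            pre_e = Metabolite(f"{precursor}_e", name=f"{name} precursor", compartment="e")
            pre_c = Metabolite(f"{precursor}_c", name=f"{name} precursor", compartment="c")
            mid_c = Metabolite(f"int{name}_c", name=f"{name} intermediate", compartment="c")
            ex_pre = Reaction(f"EX_{precursor}_e", lower_bound=0, upper_bound=WIDE_BOUND)
            ex_pre.add_metabolites({pre_e: -1})
            t_pre = Reaction(f"T_{precursor}", lower_bound=0, upper_bound=WIDE_BOUND)
            t_pre.add_metabolites({pre_e: -1, pre_c: 1})
            step1 = Reaction(f"S1_{name}", lower_bound=0, upper_bound=cap)
            step1.add_metabolites({pre_c: -1, mid_c: 1})
            step2 = Reaction(f"S2_{name}", lower_bound=0, upper_bound=cap)
            step2.add_metabolites({mid_c: -1, vit_c: 1})
            reactions += [ex_pre, t_pre, step1, step2]
            if name in spec.exporters:
                vit_e = Metabolite(f"{member}_e", name=f"{name} active form", compartment="e")
                t_out = Reaction(f"TEX_{member}", lower_bound=0, upper_bound=WIDE_BOUND)
                t_out.add_metabolites({vit_c: -1, vit_e: 1})
                ex_vit = Reaction(f"EX_{member}_e", lower_bound=0, upper_bound=WIDE_BOUND)
                ex_vit.add_metabolites({vit_e: -1})
                reactions += [t_out, ex_vit]

    model.add_reactions(reactions)
    model.objective = "biomass"

    status_of = {AUXOTROPH: ESSENTIAL, SYNTHESIZER: OPTIONAL, INDIFFERENT: NON_NUTRIENT}
    truth = pd.DataFrame(
        [
            {
                "strain": spec.strain_id,
                "family": name,
                "status": status_of[spec.phenotypes[name]],
                "exports": name in spec.exporters,
                "vitamin_in_minimal_medium": spec.phenotypes[name] == AUXOTROPH,
            }
            for name in sorted(spec.phenotypes)
        ],
        columns=["strain", "family", "status", "exports", "vitamin_in_minimal_medium"],
    )
    return model, truth


def rich_medium(model: cobra.Model, rate: float = RICH_RATE) -> Medium:
    """Every exchange of the model opened at a common uptake rate."""
    return {rxn.id: rate for rxn in model.exchanges}


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

def generate_panel(
    n_strains: int,
    prototroph_fraction: float,
    seed: int,
    families: Sequence[VitaminFamily] | None = None,
    exporter_probability: float = 0.3,
    out_dir: str | Path | None = None,
) -> tuple[list[cobra.Model], pd.DataFrame, list[StrainSpec]]:
    """Seeded panel of toy strains with exactly ``round(n * fraction)``
    prototrophs (deterministic assignment: the first strains are the
    prototrophs; every other strain gets at least one auxotrophy).

    When ``out_dir`` is given, writes per-strain JSON models, the ground
    truth TSV and a manifest (seed plus a hash of the specs), so repeated
    calls are byte-identical.
    """
    if not 0 <= prototroph_fraction <= 1:
        raise ContractError("prototroph_fraction must be in [0, 1]")
    if families is None:
        families = default_family_table()
    names = [f.name for f in families]
    n_prototrophs = round(n_strains * prototroph_fraction)
    rng = np.random.default_rng(seed)
    specs: list[StrainSpec] = []
    for i in range(n_strains):
        strain_id = f"SYN{i:04d}"
        if i < n_prototrophs:
            choices = [SYNTHESIZER, INDIFFERENT]
            phenotypes = {
                name: choices[rng.integers(len(choices))] for name in names
            }
        else:
            phenotypes = {
                name: PHENOTYPES[rng.choice(3, p=[0.4, 0.35, 0.25])]
                for name in names
            }
            if AUXOTROPH not in phenotypes.values():
                forced = names[rng.integers(len(names))]
                phenotypes[forced] = AUXOTROPH
        exporters = frozenset(
            name for name, p in phenotypes.items()
            if p == SYNTHESIZER and rng.random() < exporter_probability
        )
        specs.append(StrainSpec(strain_id, phenotypes, exporters))

    models, truths = [], []
    for spec in specs:
        model, truth = generate_strain_model(spec, families)
        models.append(model)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for model in models:
            write_model(model, out_dir / f"{model.id}.json")
        truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
        spec_blob = json.dumps(
            [
                {
                    "strain_id": s.strain_id,
                    "phenotypes": s.phenotypes,
                    "exporters": sorted(s.exporters),
                }
                for s in specs
            ],
            sort_keys=True,
        )
        manifest = {
            "n_strains": n_strains,
            "prototroph_fraction": prototroph_fraction,
            "n_prototrophs": n_prototrophs,
            "seed": seed,
            "families": names,
            "spec_sha256": hashlib.sha256(spec_blob.encode()).hexdigest(),
        }
        (out_dir / "panel_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return models, truth, specs
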