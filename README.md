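# vitaprof

High-throughput profiling of vitamin requirements and biosynthetic
capabilities for genome-scale metabolic models (GSMs), with the downstream
community analyses that vitamin exchange potential supports: capability
grouping, complementarity networks, functional redundancy and a random-group
null model.

## The problem

Gut bacteria differ in which cofactors (B vitamins and quinones) they must
obtain from their environment (*essential*), which they can make from media
precursors when the active form is absent (*optional*), and which play no
role in their metabolism at all (*non-nutrients*). These per-strain traits
are not readable from pathway presence/absence alone — whether a pathway can
actually run depends on the whole network and the medium. Flux balance
analysis (FBA) over a GSM answers the question mechanistically: maximize the
biomass flux `v_bio` subject to steady state `S·v = 0` and bounds
`lb ≤ v ≤ ub`, where exchange lower bounds encode the medium.

`vitaprof` implements the full screen:

1. **Media design** — per-strain anaerobic minimal media at a target growth
   of 0.8 gDW/h, pooled into a universal defined medium (UDM); removing the
   assessed vitamin families (members only, precursors kept) yields the
   vitamin-free medium (VFM).
2. **Requirements branch** — growth is tested on all `2^n` combinatorial
   formulations (VFM plus every subset of `n` vitamin families) against a
   viability threshold of 0.09 gDW/h; a family is *essential* when it is
   present in every growth-positive formulation. Because enriching a medium
   can only relax the LP, rows are monotone and an incremental shortcut
   skips formulations that contain a known-sufficient subset.
3. **Capabilities branch** — for each family, growth on UDM−1 (UDM minus
   that family) plus a synthesis-and-utilization test: the parsimonious flux
   solution must both produce and consume the family's active forms.
   *Optional* = synthesized and not essential; neither = non-nutrient.
   An export variant forces a small secretion flux and re-checks growth.
4. **Community layer** — hierarchical clustering of requirement profiles
   (Hamming distance), named capability groups (core requirement set with
   +/++ bands for extra requirements), provider→requirer complementarity
   networks, the functional redundancy score `fr = vs/(nv·nm)` (synthesized
   entries over assessed vitamins × members), and a seeded random-group null
   model over the (fr, % prototrophs) plane.

A synthetic-model generator (`vitaprof.synth`) builds small anaerobic toy
GSMs with configurable per-family phenotypes (auxotroph / synthesizer /
indifferent, optional exporters) and machine-readable ground truth, so the
entire pipeline is testable without external model collections.

## Worked example

```python
from vitaprof import (
    AssessmentConfig, default_family_table, generate_panel, rich_medium,
    compute_minimal_medium, pool_udm, remove_families,
    enumerate_formulations, profile_strain,
)

families = default_family_table()          # B1 B2 B3 B5 B6 B9 B12 K
models, truth, _ = generate_panel(6, prototroph_fraction=1/3, seed=42)

minimal_media = [compute_minimal_medium(m, rich_medium(m), 0.8) for m in models]
udm = pool_udm(minimal_media)
vfm = remove_families(udm, families)
formulations = enumerate_formulations(vfm, families, udm)
print(f"UDM components: {len(udm)}   VFM components: {len(vfm)}   "
      f"formulations: {len(formulations)}")

config = AssessmentConfig()                # threshold 0.09 gDW/h
for model in models:
    profile, result, synthesized, exports = profile_strain(
        model, udm, vfm, formulations, families, config
    )
    print(f"{model.id}: essential={sorted(profile.essential) or '-'} "
          f"optional={sorted(profile.optional) or '-'} "
          f"prototroph={profile.is_prototroph} "
          f"(solved {result.n_solves}/256 media)")
```

prints

```
UDM components: 16   VFM components: 9   formulations: 256
SYN0000: essential=- optional=['B1', 'B12', 'B5', 'B6'] prototroph=True (solved 1/256 media)
SYN0001: essential=- optional=['B12', 'B2', 'B5', 'B9'] prototroph=True (solved 1/256 media)
SYN0002: essential=['B1', 'B5'] optional=['B2', 'B9'] prototroph=False (solved 193/256 media)
SYN0003: essential=['B1', 'B5', 'B6'] optional=['B12', 'B2', 'B3', 'K'] prototroph=False (solved 225/256 media)
SYN0004: essential=['B2', 'B3', 'B6'] optional=['B1', 'B9'] prototroph=False (solved 225/256 media)
SYN0005: essential=['B1', 'B12', 'B9'] optional=['B2', 'B3', 'B5'] prototroph=False (solved 225/256 media)
```

Reading the output: the two prototrophs grow on the VFM itself, so the
monotone shortcut settles all 256 formulations from a single solve; for
auxotrophic strains the essential set is exactly the families whose absence
blocks growth, and the optional set lists families the strain synthesizes on
the corresponding single-omission medium. Statuses always partition the
families — no family is ever both essential and optional for one strain.

The same pipeline is available from the shell (each stage writes its tables
plus a `manifest.json`):

```sh
vitaprof simulate --n-strains 20 --seed 7 --out-dir panel/
vitaprof udm --models-dir panel/ --out-dir media/
vitaprof essential --models-dir panel/ --media-dir media/ --out-dir run/
vitaprof optional  --models-dir panel/ --media-dir media/ --out-dir run/
vitaprof profile --run-dir run/ --out-dir run/
vitaprof null --profiles run/profiles.tsv --n-groups 1000 --group-size 9 \
    --seed 11 --out-dir null/
```

## Layout

| module               | contents                                                  |
| -------------------- | --------------------------------------------------------- |
| `vitaprof.core`      | model I/O (SBML-FBC / JSON via cobrapy), media, FBA/pFBA, turnover |
| `vitaprof.families`  | vitamin family table (members, precursors), id matching   |
| `vitaprof.media`     | minimal media, UDM pooling, VFM, combinatorial formulations |
| `vitaprof.profiling` | both assessment branches, export variant, OD concordance  |
| `vitaprof.groups`    | profile clustering, capability-group assignment           |
| `vitaprof.modules`   | interaction modules, complementarity networks, null model |
| `vitaprof.synth`     | synthetic toy GSM generator with ground truth             |
| `vitaprof.cli`       | `vitaprof` command-line entry point                       |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
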