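# Methods

## Model and growth semantics

A genome-scale model is a stoichiometric network with two compartments
(intracellular, extracellular), flux bounds, exchange reactions (one
extracellular metabolite each, coefficient −1; positive flux = secretion,
negative = uptake) and a single biomass objective. Growth is the biomass
objective value of the FBA linear program — maximize `v_bio` subject to
`S·v = 0` and `lb ≤ v ≤ ub` — reported in gDW/h and used directly as the
growth number without unit conversion, even where thresholds are motivated
by doubling-time (h⁻¹) arguments. cobrapy with the GLPK backend supplies the
containers, SBML-FBC/JSON I/O and the solver; all screening logic sits above
that layer.

A medium is a mapping from exchange-reaction ids to strictly positive
maximum uptake rates. Applying a medium sets the listed exchanges'
lower bounds to minus their rate and closes every unlisted exchange to
uptake; secretion bounds are untouched. Medium keys a model cannot
transport are skipped with a warning by default (strict mode available):
a pooled community medium necessarily lists components individual strains
lack transporters for.

## Media design

Per-strain minimal media are computed at a fixed target growth of
0.8 gDW/h (a proxy for optimal growth) by minimizing total import flux at
that growth and then greedily pruning retained components in lexicographic
id order; the result is irreducible — removing any single retained component
drops growth below target. An exact component-count MILP is available behind
a flag (`exact=True`) but is not the default; on the small networks used in
tests the two agree. Strains that cannot reach the target on their full
candidate medium raise a named infeasibility error and are excluded (with a
logged warning) by the CLI rather than aborting a panel run.

The universal defined medium (UDM) pools all per-strain minimal media:
union of components, each at the **maximum** rate seen across strains. The
maximum guarantees every strain's own minimal medium is dominated by the
UDM, so every strain grows on it; how pooled rates should be set is
otherwise an open design choice. The vitamin-free medium (VFM) removes the
member exchanges (active forms and analogues) of all assessed families; the
precursor components stay, so de novo biosynthesis remains possible — this
is what separates "can synthesize" from "merely does not need".

## The two branches

**Requirements.** All `2^n` formulations (VFM + each family subset, member
exchanges at their UDM rates; a member the UDM never contained gets a
default rate of 10 mmol/gDW/h) are evaluated against a viability threshold
of 0.09 gDW/h, inclusive, with a flux/growth tolerance of 1e-6. Since
relaxing exchange bounds can only grow the LP's feasible region, the Boolean
row is monotone in the subset order. Consequences used:

* the *essential set* — families present in every growth-positive
  formulation — is well defined, and equals the complement of what can be
  dropped; disjunctive requirements ("B1 or B2 suffices") make neither
  alternative essential and surface instead as multiple *minimal sufficient
  sets* (the antichain of minimal growth-positive subsets);
* the *incremental shortcut*: iterating by ascending subset size, any
  formulation containing a known-sufficient set is marked growth-positive
  without solving. The recorded row provably equals the exhaustive one
  (asserted cell-for-cell in tests over every phenotype combination with
  four families).

If no formulation supports growth, the strain requires nutrients beyond the
assessed panel: the row is all-zero and the strain is flagged; the essential
set then degenerates to all assessed families (intersection over an empty
collection), kept for consistency with the definition.

**Capabilities.** For each family the members are removed from the full UDM
(UDM−1). The strain is a synthesizer iff growth stays at or above threshold
*and* the parsimonious (pFBA) solution's internal reactions both produce and
consume the family's intracellular active forms at ≥ 1e-6 mmol/gDW/h. The
parsimonious solution is used because plain FBA optima are degenerate and a
zero-flux pathway in one optimum may carry flux in another; pFBA gives a
canonical, minimal-total-flux witness. Consumption counts the biomass
pseudo-reaction as a utilizer. Growth without any producing/consuming
reaction is the non-nutrient pattern, not synthesis.

**Export.** On UDM−1, each exchange carrying a family member is forced to
secrete at least `export_epsilon` (default 0.001 mmol/gDW/h; no empirical
value exists, so it is configurable) and growth is re-checked. Strains
lacking any member exchange cannot export by construction.

**Statuses.** essential / optional (= synthesized ∧ ¬essential) /
non-nutrient partition the families per strain; a family reported both
essential and synthesized would contradict the branch definitions and
raises an internal-consistency error rather than being silently resolved.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `growth_threshold` | 0.09 | gDW/h | six-to-eight-hour doubling time, the slowest growth compatible with persistence against gut transit |
| `minimal_medium_target` | 0.8 | gDW/h | optimal-growth proxy for media design |
| `flux_tolerance` | 1e-6 | mmol/gDW/h | LP hygiene; also the growth-comparison tolerance |
| `export_epsilon` | 0.001 | mmol/gDW/h | small forced secretion; arbitrary but configurable |
| `incremental_shortcut` | on | — | exact under monotonicity, large speedup |

Boolean cells use inclusive comparison (growth ≥ threshold − tolerance).

## Community layer

Clustering of requirement profiles is hierarchical agglomerative (average or
complete linkage) on Hamming distances between binary essential-status
vectors, with profiles pre-sorted by strain id so output is deterministic
under input permutation. Capability groups are *user-supplied* definitions —
a core family set plus a band for extra requirements (`+` = 1–3 extras,
`++` = >3, no suffix = exact) — because the reference grouping was finalized
by manual inspection and is not algorithmically recoverable; prototrophs
(no essential families) always map to a dedicated group, and a strain
matching two definitions raises an ambiguity error listing the conflict.

Interaction modules are eligible when they have ≥ 5 original members and
≥ 50% of them map to profiled strains (genus+species token prefix matching;
multi-candidate species enumerate one module version per resolution). Module
summaries report `vs` (synthesized entries over members), the functional
redundancy score `fr = vs/(nv·nm)`, the prototroph percentage, and
complementarity completeness: every family required by any member has at
least one in-module provider. `nv` defaults to the number of assessed
families but is an explicit parameter, since reference analyses have used
nv = 7 with eight assessed families and the dropped family is not stated —
we parameterize rather than guess.

The null model draws groups uniformly without replacement within a group
(strains may recur across groups) from the profile pool, seeded, and
summarizes them identically. The empirical per-group prototroph-count
distribution is validated against the closed-form hypergeometric law
Hypergeom(N, K, n) by a chi-square goodness-of-fit test — an oracle
independent of the sampler. Region classification over the
(fr, prototroph %) plane uses the random-cloud box (defaults 0.3–0.7 fr ×
0–40%), boundaries closed on the random-like side; below the box with zero
prototrophs is complementarity-driven, above it in both axes is
exchange-independent. Points matching none of those three predicates are
reported as `unclassified` instead of being forced into the nearest label.

## Synthetic models

The generator emulates the strain archetypes the screen distinguishes, per
family: *auxotroph* (active form importable and in biomass, no pathway),
*synthesizer* (active form in biomass, made by a two-step pathway from an
importable precursor — the minimal structure separating "precursor in the
medium" from "pathway in the genome"), *indifferent* (no reactions touch the
family). Exporters (a subset of synthesizers) get an outward transporter and
secretion exchange with surplus pathway capacity; capping the pathway at the
biomass-implied flux produces the export-negative control. The backbone is a
single substrate exchange/transport pair feeding biomass (1 mmol per gDW);
active vitamins enter biomass at 0.01 mmol/gDW; rich media open every
exchange at 10 mmol/gDW/h; no oxygen exchange exists (anaerobic flavor).
Panels assign exactly `round(n · prototroph_fraction)` prototrophs
deterministically (every non-prototroph is forced to carry at least one
auxotrophy) and are byte-reproducible from their seed.

What the generator does *not* emulate: realistic network size and
redundancy, alternative salvage routes, analogue multiplicity within a
family, growth-rate heterogeneity, or curation noise in real
reconstructions. Passing the ground-truth recovery tests therefore shows
the pipeline's logic is correct on networks whose truth is known by
construction — not that predictions on real reconstructions are accurate,
which inherits all the usual caveats of automated GSMs (inflated growth
rates, missing transporters, undescribed exchange mechanisms).

## Problem sizes used in the test suite

The suite exercises the full pipeline on seeded panels of 10–50 strains ×
8 families (256 formulations per strain), 100 random model/medium pairs for
the LP properties, every phenotype combination over 4 families for the
shortcut-equivalence check, and 10,000 null-model draws for the
goodness-of-fit test; these sizes give exact or tightly-bounded expectations
while keeping a full run under half a minute on one CPU.

## Known limitations

* Single-species FBA only: no community (joint) FBA, no thermodynamic or
  kinetic constraints, no dynamic simulation.
* The essential-set definition relies on medium monotonicity of the LP; it
  is exact for FBA but would not transfer to models with regulatory switches.
* Greedy minimal media are irreducible but not guaranteed minimum-cardinality
  (use `exact=True` for the MILP when that matters).
* `od_concordance` treats the 20%/80% maxOD bands as hard cutoffs; values on
  the band edges are inconclusive.
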