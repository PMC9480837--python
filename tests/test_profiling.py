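"""The two assessment branches, the export variant, classification and
in vitro concordance."""

import dataclasses

import cobra
import pandas as pd
import pytest
from cobra import Metabolite, Reaction

from vitaprof import (
    AssessmentConfig,
    assess_essential,
    assess_export,
    assess_synthesis,
    build_profile,
    default_family_table,
    enumerate_formulations,
    od_concordance,
    rich_medium,
)
from vitaprof.errors import ContractError, InternalConsistencyError
from vitaprof.profiling import (
    ESSENTIAL,
    NON_NUTRIENT,
    OPTIONAL,
    boolean_table,
    profiles_table,
)
from vitaprof.synth import StrainSpec, generate_strain_model


@pytest.fixture(scope="module")
def table():
    return {f.name: f for f in default_family_table()}


def make_strain(phenotypes, exporters=(), pathway_capacity=None):
    spec = StrainSpec(
        "strain",
        phenotypes,
        frozenset(exporters),
        pathway_capacity=dict(pathway_capacity or {}),
    )
    model, _ = generate_strain_model(spec)
    return model


def design(model, families):
    """UDM/VFM/formulations straight from the strain's own rich medium."""
    udm = rich_medium(model)
    from vitaprof import remove_families

    vfm = remove_families(udm, families)
    return udm, vfm, enumerate_formulations(vfm, families, udm)


class TestAssessEssential:
    def test_b1_auxotroph_splits_the_row_in_half(self, families, config):
        model = make_strain(
            {"B1": "auxotroph", **{n: "synthesizer" for n in
                                   ("B2", "B3", "B5", "B6", "B9", "B12", "K")}}
        )
        udm, vfm, formulations = design(model, families)
        result = assess_essential(model, vfm, formulations, config)
        assert result.essential == {"B1"}
        assert result.minimal_sufficient_sets == [frozenset({"B1"})]
        for formulation in formulations:
            expected = int("B1" in formulation.included_families)
            assert result.row[formulation.label] == expected
        assert sum(result.row.values()) == 128

    def test_prototroph_gives_all_ones_row(self, families, config):
        model = make_strain({n: "synthesizer" for n in
                             ("B1", "B2", "B3", "B5", "B6", "B9", "B12", "K")})
        udm, vfm, formulations = design(model, families)
        result = assess_essential(model, vfm, formulations, config)
        assert result.essential == frozenset()
        assert all(v == 1 for v in result.row.values())
        assert result.minimal_sufficient_sets == [frozenset()]
        # shortcut means only the VFM formulation ever hits the solver
        assert result.n_solves == 1

    def test_disjunctive_requirement_yields_two_minimal_sets(self, table, config):
        """A strain satisfiable by B1 OR B2 has an empty essential set and two
        minimal sufficient sets."""
        model = cobra.Model("either")
        mets = {
            mid: Metabolite(mid, compartment="e" if mid.endswith("_e") else "c")
            for mid in ("sub_e", "sub_c", "vitB1_e", "vitB2_e", "cof_c")
        }
        reactions = []
        for token in ("sub", "vitB1", "vitB2"):
            ex = Reaction(f"EX_{token}_e", lower_bound=0, upper_bound=1000)
            ex.add_metabolites({mets[f"{token}_e"]: -1})
            reactions.append(ex)
        t_sub = Reaction("T_sub", lower_bound=0, upper_bound=1000)
        t_sub.add_metabolites({mets["sub_e"]: -1, mets["sub_c"]: 1})
        salvage1 = Reaction("T_vitB1", lower_bound=0, upper_bound=1000)
        salvage1.add_metabolites({mets["vitB1_e"]: -1, mets["cof_c"]: 1})
        salvage2 = Reaction("T_vitB2", lower_bound=0, upper_bound=1000)
        salvage2.add_metabolites({mets["vitB2_e"]: -1, mets["cof_c"]: 1})
        biomass = Reaction("biomass", lower_bound=0, upper_bound=1000)
        biomass.add_metabolites({mets["sub_c"]: -1, mets["cof_c"]: -0.01})
        model.add_reactions(reactions + [t_sub, salvage1, salvage2, biomass])
        model.objective = "biomass"

        families = [table["B1"], table["B2"]]
        udm = rich_medium(model)
        from vitaprof import remove_families

        vfm = remove_families(udm, families)
        formulations = enumerate_formulations(vfm, families, udm)
        result = assess_essential(model, vfm, formulations, AssessmentConfig())
        assert result.essential == frozenset()
        assert set(result.minimal_sufficient_sets) == {
            frozenset({"B1"}),
            frozenset({"B2"}),
        }
        assert [result.row[l] for l in ("VFM", "B1", "B2", "B1+B2")] == [0, 1, 1, 1]

    def test_shortcut_equals_exhaustive_for_small_panels(self, families, config):
        """Cell-for-cell equivalence of the incremental shortcut, V <= 4."""
        phenos = ["auxotroph", "synthesizer", "indifferent"]
        specs = [
            {"B1": phenos[i % 3], "B2": phenos[(i + 1) % 3],
             "B3": phenos[(i + 2) % 3], "B5": phenos[i % 2]}
            for i in range(6)
        ]
        exhaustive_config = dataclasses.replace(config, incremental_shortcut=False)
        for phenotypes in specs:
            model = make_strain(phenotypes)
            udm, vfm, formulations = design(model, families[:4])
            fast = assess_essential(model, vfm, formulations, config)
            slow = assess_essential(model, vfm, formulations, exhaustive_config)
            assert fast.row == slow.row
            assert fast.essential == slow.essential
            assert fast.n_solves <= slow.n_solves == len(formulations)

    def test_rows_are_monotone_in_the_subset_order(self, panel, config):
        formulations = panel["formulations"]
        by_label = {f.label: f.included_families for f in formulations}
        for model in panel["models"][:4]:
            result = assess_essential(model, panel["vfm"], formulations, config)
            for a in formulations:
                for b in formulations:
                    if by_label[a.label] <= by_label[b.label]:
                        assert result.row[a.label] <= result.row[b.label]

    def test_no_growth_anywhere_flags_beyond_panel(self, families, config):
        model = make_strain({"B1": "auxotroph"})
        # VFM lacking the substrate: nothing can grow
        formulations = enumerate_formulations(
            {}, families[:1], {"EX_vitB1_e": 10.0}
        )
        result = assess_essential(model, {}, formulations, config)
        assert result.requires_beyond_panel
        assert all(v == 0 for v in result.row.values())


class TestAssessSynthesis:
    def test_synthesizer_detected_on_single_omission(self, table, config):
        model = make_strain({"B12": "synthesizer", "B1": "auxotroph"})
        udm = rich_medium(model)
        assert assess_synthesis(model, udm, table["B12"], config) is True

    def test_growth_without_family_reactions_is_not_synthesis(self, table, config):
        # grows fine on UDM-B3 but has no B3 reactions at all: non-nutrient
        model = make_strain({"B3": "indifferent", "B1": "synthesizer"})
        udm = rich_medium(model)
        assert assess_synthesis(model, udm, table["B3"], config) is False

    def test_auxotroph_fails_the_growth_gate(self, table, config):
        model = make_strain({"B1": "auxotroph"})
        udm = rich_medium(model)
        assert assess_synthesis(model, udm, table["B1"], config) is False

    def test_biomass_precursor_consistency(self, table, config):
        """If a member is a biomass precursor, absent from the medium, and the
        strain still grows, synthesis must be reported."""
        model = make_strain({"B2": "synthesizer"})
        udm = rich_medium(model)
        from vitaprof import remove_families
        from vitaprof.core import growth_on

        depleted = remove_families(udm, [table["B2"]])
        assert growth_on(model, depleted) >= config.growth_threshold
        assert assess_synthesis(model, udm, table["B2"], config) is True


class TestAssessExport:
    def test_exporter_with_surplus_capacity(self, table, config):
        model = make_strain({"B3": "synthesizer"}, exporters=("B3",))
        udm = rich_medium(model)
        assert assess_export(model, udm, table["B3"], config) is True

    def test_capacity_equal_to_demand_cannot_export(self, table, config):
        # pathway capped so that forcing secretion drops growth below threshold
        model = make_strain(
            {"B3": "synthesizer"},
            exporters=("B3",),
            pathway_capacity={"B3": 0.0015},
        )
        udm = rich_medium(model)
        assert assess_synthesis(model, udm, table["B3"], config) is True
        assert assess_export(model, udm, table["B3"], config) is False

    def test_no_member_exchange_means_no_export(self, table, config):
        model = make_strain({"B3": "synthesizer"})  # no exporter exchange
        udm = rich_medium(model)
        assert assess_export(model, udm, table["B3"], config) is False


class TestBuildProfile:
    def test_two_five_one_partition(self, families):
        profile = build_profile(
            "prevotella_like",
            {"B1", "K"},
            {n: n in {"B2", "B3", "B5", "B6", "B9"} for n in
             ("B1", "B2", "B3", "B5", "B6", "B9", "B12", "K")},
            families,
        )
        assert profile.n_essential == 2
        assert profile.n_optional == 5
        assert profile.status["B12"] == NON_NUTRIENT
        assert not profile.is_prototroph

    def test_all_synthesizer_prototroph(self, families):
        profile = build_profile(
            "proto", set(), {f.name: True for f in families}, families
        )
        assert profile.is_prototroph and profile.n_optional == 8

    def test_degenerate_prototroph_with_nothing(self, families):
        profile = build_profile("inert", set(), {}, families)
        assert profile.is_prototroph
        assert all(s == NON_NUTRIENT for s in profile.status.values())

    def test_essential_and_synthesized_clash_raises(self, families):
        with pytest.raises(InternalConsistencyError):
            build_profile("bad", {"B1"}, {"B1": True}, families)

    def test_statuses_partition_families(self, families):
        profile = build_profile(
            "p", {"B1"}, {"B2": True}, families
        )
        statuses = {ESSENTIAL: 0, OPTIONAL: 0, NON_NUTRIENT: 0}
        for status in profile.status.values():
            statuses[status] += 1
        assert sum(statuses.values()) == len(families)
        assert not (profile.essential & profile.optional)


class TestTables:
    def test_boolean_table_shape_and_labels(self, panel, config):
        results = [
            assess_essential(m, panel["vfm"], panel["formulations"], config)
            for m in panel["models"][:3]
        ]
        frame = boolean_table(results)
        assert frame.shape == (3, 256)
        assert list(frame.columns) == [f.label for f in panel["formulations"]]

    def test_profiles_table_long_format(self, families):
        profile = build_profile("s", {"B1"}, {"B2": True}, families)
        frame = profiles_table([profile])
        assert set(frame.columns) == {"strain", "family", "status"}
        assert len(frame) == 8


class TestODConcordance:
    @pytest.fixture
    def profiles(self, families):
        return {
            "s1": build_profile("s1", {"B2"}, {}, families),
            "s2": build_profile("s2", set(), {"B2": True}, families),
        }

    def test_verdicts_and_rate(self, profiles):
        od = pd.DataFrame(
            [
                {"strain": "s1", "family": "B2", "pct_max_od": 5.0},    # match
                {"strain": "s2", "family": "B2", "pct_max_od": 95.0},   # match
                {"strain": "s1", "family": "B2", "pct_max_od": 95.0},   # mismatch
                {"strain": "s1", "family": "B2", "pct_max_od": 50.0},   # inconclusive
            ]
        )
        frame, rate = od_concordance(profiles, od)
        assert list(frame.verdict) == ["match", "match", "mismatch", "inconclusive"]
        assert rate == pytest.approx(2 / 3)

    def test_band_boundaries_are_inconclusive(self, profiles):
        od = pd.DataFrame(
            [
                {"strain": "s1", "family": "B2", "pct_max_od": 20.0},
                {"strain": "s1", "family": "B2", "pct_max_od": 80.0},
            ]
        )
        frame, rate = od_concordance(profiles, od)
        assert list(frame.verdict) == ["inconclusive", "inconclusive"]
        assert rate != rate  # NaN: no conclusive pairs

    def test_unknown_strain_is_a_contract_error(self, profiles):
        od = pd.DataFrame([{"strain": "nope", "family": "B2", "pct_max_od": 5.0}])
        with pytest.raises(ContractError):
            od_concordance(profiles, od)
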