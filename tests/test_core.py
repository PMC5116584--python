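"""Binding rules, state resolution and template activity."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcalogic import (
    CircularTemplate,
    Ligand,
    OperatorSite,
    ReactionSystem,
    RegulationMode,
    RepressorSpec,
    SpeciesRegistry,
    SpeciesState,
    catalogue_design,
    evaluate_truth_table,
    resolve_state,
    site_occupied,
    switch_matrix,
    system_activity,
    template_active,
)


def _site(registry, repressor):
    spec = registry.repressor(repressor)
    return OperatorSite(operator_id=spec.operator_id, cognate_repressor=repressor)


class TestResolveState:
    def test_single_input_releases_one_repressor(self, registry):
        system = catalogue_design("AND", registry)
        state = resolve_state(system, {"IPTG": 1, "D-Gal": 0})
        assert state.repressors_present == frozenset({"LacI", "GalR"})
        assert state.concentration("IPTG") == 5.0
        assert state.concentration("D-Gal") == 0.0

    def test_all_zero_assignment_equals_constants(self, registry):
        system = catalogue_design("NOR", registry)
        zero = {name: 0 for name in system.input_names}
        assert resolve_state(system, zero) == system.constants

    def test_composite_input_supplies_both_species(self, registry):
        system = catalogue_design("XOR", registry)
        state = resolve_state(system, {"A": 1, "B": 0})
        assert state.concentration("IPTG") == 5.0
        assert state.concentration("L-Trp") == 1.0
        assert state.concentration("D-Gal") == 0.0
        assert state.concentration("SAM") == 0.0

    def test_repressor_supplied_by_input(self, registry):
        system = catalogue_design("ORN1", registry)
        state = resolve_state(system, {"IPTG": 0, "LacI": 1})
        assert "LacI" in state.repressors_present

    def test_unknown_input_name_rejected(self, registry):
        system = catalogue_design("AND", registry)
        with pytest.raises(ValueError, match="assignment keys"):
            resolve_state(system, {"IPTG": 1, "bogus": 0})


class TestSiteOccupancy:
    @pytest.mark.parametrize(
        "repressor, present, ligands, expected",
        [
            # inducer-regulated: bound unless induced
            ("LacI", True, {}, 1),
            ("LacI", True, {"IPTG": 5.0}, 0),
            ("LacI", False, {}, 0),
            # anti-inducer-regulated: bound only when armed
            ("TrpR", True, {}, 0),
            ("TrpR", False, {"L-Trp": 1.0}, 0),
            ("TrpR", True, {"L-Trp": 1.0}, 1),
            # cross-reactivity thresholds: 5 mM D-Gal does not induce LacI,
            # 2 mM SAM does arm TrpR (cross-threshold 1.5 mM)
            ("LacI", True, {"D-Gal": 5.0}, 1),
            ("LacI", True, {"D-Gal": 20.0}, 0),
            ("TrpR", True, {"SAM": 2.0}, 1),
            ("TrpR", True, {"SAM": 1.0}, 0),
        ],
    )
    def test_binding_rules(self, registry, repressor, present, ligands, expected):
        state = SpeciesState(
            frozenset({repressor}) if present else frozenset(), ligands
        )
        assert site_occupied(_site(registry, repressor), registry, state) == expected

    @settings(derandomize=True, max_examples=60)
    @given(
        concs=st.lists(
            st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
            min_size=2,
            max_size=8,
        ),
        repressor=st.sampled_from(["LacI", "GalR", "TrpR", "MetJ"]),
    )
    def test_occupancy_monotone_in_cognate_ligand(self, registry, concs, repressor):
        """Inducer-type occupancy never increases, anti-inducer-type never
        decreases, as the cognate ligand concentration rises."""
        spec = registry.repressor(repressor)
        site = _site(registry, repressor)
        occ = [
            site_occupied(
                site,
                registry,
                SpeciesState(frozenset({repressor}), {spec.cognate_ligand: c}),
            )
            for c in sorted(concs)
        ]
        if spec.mode is RegulationMode.INDUCER_REGULATED:
            assert occ == sorted(occ, reverse=True)
        else:
            assert occ == sorted(occ)


class TestTemplateActivity:
    def test_series_and_gate_needs_both_inducers(self, registry):
        system = catalogue_design("AND", registry)
        template = system.templates[0]
        both = SpeciesState(
            frozenset({"LacI", "GalR"}), {"IPTG": 5.0, "D-Gal": 5.0}
        )
        one = SpeciesState(frozenset({"LacI", "GalR"}), {"IPTG": 5.0})
        assert template_active(template, registry, both) == 1
        assert template_active(template, registry, one) == 0

    def test_no_repressors_means_active(self, registry):
        system = catalogue_design("ALL", registry)
        assert template_active(system.templates[0], registry, SpeciesState()) == 1

    def test_repressor_replacement_keeps_inhibition(self, registry):
        """On a GalR+TrpR series template, D-Gal releases GalR but L-Trp arms
        TrpR, so the template stays blocked when both effectors are present."""
        system = catalogue_design("ANDN", registry)
        state = SpeciesState(
            frozenset({"GalR", "TrpR"}), {"D-Gal": 5.0, "L-Trp": 1.0}
        )
        assert template_active(system.templates[0], registry, state) == 0

    def test_activity_is_conjunction_over_sites(self, registry):
        """Exhaustive check against the product form over up to 4 sites and
        every subset of repressors and effectors."""
        reps = ["LacI", "GalR", "TrpR", "MetJ"]
        sites = [_site(registry, r) for r in reps]
        template = CircularTemplate("T", sites)
        ligs = ["IPTG", "D-Gal", "SAM", "L-Trp"]
        for rep_subset in itertools.chain.from_iterable(
            itertools.combinations(reps, k) for k in range(5)
        ):
            for lig_bits in itertools.product([0, 1], repeat=4):
                state = SpeciesState(
                    frozenset(rep_subset),
                    {
                        lig: registry.ligand(lig).working_concentration_mM
                        for lig, bit in zip(ligs, lig_bits)
                        if bit
                    },
                )
                product = 1
                for site in sites:
                    product *= 1 - site_occupied(site, registry, state)
                assert template_active(template, registry, state) == product

    def test_rotation_invariance(self, registry):
        """Rotating a circular template's site order never changes its table."""
        for gate in ("AND", "NOR", "THREE_INPUT", "XNOR"):
            system = catalogue_design(gate, registry)
            base = evaluate_truth_table(system)
            template = system.templates[0]
            for k in range(1, len(template.sites)):
                rotated = ReactionSystem(
                    name=system.name,
                    templates=(template.rotated(k),) + system.templates[1:],
                    constants=system.constants,
                    input_map=system.input_map,
                    registry=registry,
                )
                assert evaluate_truth_table(rotated).outputs == base.outputs


class TestSystemActivity:
    def test_parallel_or_gate_half_active(self, registry):
        system = catalogue_design("OR", registry)
        assert system_activity(system, {"IPTG": 1, "D-Gal": 0}) == (1, 0.5)

    def test_parallel_nand_gate_fully_inhibited(self, registry):
        system = catalogue_design("NAND", registry)
        assert system_activity(system, {"SAM": 1, "L-Trp": 1}) == (0, 0.0)

    def test_bare_template_fully_active(self, registry):
        system = ReactionSystem(
            name="bare",
            templates=[CircularTemplate("T", [])],
            constants=SpeciesState(),
            input_map={"X": frozenset()},
            registry=registry,
        )
        assert system_activity(system, {"X": 0}) == (1, 1.0)


class TestOrthogonality:
    def test_switch_matrix_diagonal_at_working_concentrations(self, registry):
        matrix = switch_matrix(registry)
        for lig in matrix.index:
            for rep in matrix.columns:
                cognate = registry.repressor(rep).cognate_ligand == lig
                assert matrix.loc[lig, rep] == int(cognate), (lig, rep)

    def test_high_dgal_cross_induces_laci(self, registry):
        matrix = switch_matrix(registry, {"D-Gal": 20.0})
        assert matrix.loc["D-Gal", "LacI"] == 1
        assert matrix.loc["D-Gal", "GalR"] == 1

    def test_high_sam_cross_arms_trpr(self, registry):
        matrix = switch_matrix(registry, {"SAM": 2.0})
        assert matrix.loc["SAM", "TrpR"] == 1
        assert matrix.loc["SAM", "MetJ"] == 1


class TestValidation:
    def test_leak_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="leak"):
            RepressorSpec(
                "X",
                RegulationMode.INDUCER_REGULATED,
                "IPTG",
                "op",
                {"IPTG": 1.0},
                leak=1.5,
            )

    def test_missing_cognate_threshold_rejected(self):
        with pytest.raises(ValueError, match="cognate"):
            RepressorSpec(
                "X", RegulationMode.INDUCER_REGULATED, "IPTG", "op", {"D-Gal": 1.0}
            )

    def test_duplicate_repressor_on_template_rejected(self, registry):
        site = _site(registry, "LacI")
        with pytest.raises(ValueError, match="one site per repressor"):
            CircularTemplate("T", [site, site])

    def test_ligand_cannot_be_constant_and_input(self, registry):
        with pytest.raises(ValueError, match="constant"):
            ReactionSystem(
                name="bad",
                templates=[CircularTemplate("T", [_site(registry, "LacI")])],
                constants=SpeciesState(frozenset(), {"IPTG": 5.0}),
                input_map={"IPTG": frozenset({"IPTG"})},
                registry=registry,
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Ligand("X", working_concentration_mM=-1.0)
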