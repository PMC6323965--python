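"""Binding / UP / DOWN perturbations of the spring network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit import (
    PerturbationAction,
    PerturbationKind,
    PerturbationSpec,
    SiteDefinition,
    ValidationError,
    apply_perturbation,
    build_contact_network,
    enumerate_site_combinations,
    load_sites_json,
    parse_site_string,
)
from allokit.fixtures import coords_to_pdb
from allokit.structure import parse_structure


@pytest.fixture(scope="module")
def square_model():
    # 12 A square: adjacent corners bonded at cutoff 11, diagonals not
    coords = [[0, 0, 0], [12, 0, 0], [12, 12, 0], [0, 12, 0]]
    return parse_structure(coords_to_pdb(coords))


class TestSpecValidation:
    def test_alpha_constraints(self):
        site = SiteDefinition("s", ("A:1",))
        with pytest.raises(ValidationError):
            PerturbationAction(PerturbationKind.BINDING, site, 0.5)
        with pytest.raises(ValidationError):
            PerturbationAction(PerturbationKind.UP, "A:1", 1.0)
        with pytest.raises(ValidationError):
            PerturbationAction(PerturbationKind.DOWN, "A:1", 1.5)
        with pytest.raises(ValidationError):
            PerturbationAction(PerturbationKind.DOWN, "A:1", -0.1)

    def test_residue_in_two_mutation_actions_rejected(self, square_model):
        spec = PerturbationSpec(
            (
                PerturbationAction(PerturbationKind.UP, "A:1", 2.0),
                PerturbationAction(PerturbationKind.DOWN, "A:1", 0.1),
            )
        )
        with pytest.raises(ValidationError, match="more than one mutation"):
            spec.validate(square_model)

    def test_unknown_residue_named_in_error(self, square_model):
        spec = PerturbationSpec.mutation("A:99", "up")
        with pytest.raises(ValidationError, match="A:99"):
            spec.validate(square_model)

    def test_empty_site_rejected(self):
        with pytest.raises(ValidationError):
            SiteDefinition("empty", ())


class TestApplyPerturbation:
    def test_up_doubles_incident_edges_only(self, helix30):
        model, _ = helix30
        net = build_contact_network(model)
        m = model.index_of("A:10")
        out = apply_perturbation(net, PerturbationSpec.mutation(m, "up", 2.0), model)
        assert out.n_edges == net.n_edges
        for i, j in net.edges:
            factor = 2.0 if m in (i, j) else 1.0
            assert out.spring_constant(i, j) == pytest.approx(
                factor * net.spring_constant(i, j)
            )
            assert out.rest_length(i, j) == net.rest_length(i, j)

    def test_down_scales_down(self, helix30):
        model, _ = helix30
        net = build_contact_network(model)
        out = apply_perturbation(net, PerturbationSpec.mutation(0, "down", 0.1), model)
        for j in net.neighbors(0):
            assert out.spring_constant(0, j) == pytest.approx(0.1)

    def test_binding_creates_edge_beyond_cutoff(self, square_model):
        net = build_contact_network(square_model, cutoff=11.0)
        site = SiteDefinition("diag", ("A:1", "A:2"))
        # members 12 A apart: no existing edge, but within binding_pair_cutoff 15
        assert not net.has_edge(0, 1)
        out = apply_perturbation(net, PerturbationSpec.binding(site, 10.0),
                                 square_model, binding_pair_cutoff=15.0)
        assert out.has_edge(0, 1)
        assert out.spring_constant(0, 1) == pytest.approx(10.0 * net.base_k)
        assert out.rest_length(0, 1) == pytest.approx(12.0)

    def test_binding_respects_pair_cutoff(self, square_model):
        net = build_contact_network(square_model, cutoff=11.0)
        site = SiteDefinition("all", ("A:1", "A:2", "A:3", "A:4"))
        out = apply_perturbation(net, PerturbationSpec.binding(site, 10.0),
                                 square_model, binding_pair_cutoff=15.0)
        # diagonals are ~16.97 A: not created
        assert not out.has_edge(0, 2)
        assert not out.has_edge(1, 3)
        assert out.has_edge(0, 1)

    def test_empty_spec_is_identity(self, helix30):
        model, _ = helix30
        net = build_contact_network(model)
        out = apply_perturbation(net, PerturbationSpec.empty(), model)
        assert out == net

    def test_input_network_never_mutated(self, helix30):
        model, _ = helix30
        net = build_contact_network(model)
        before = {e: net.spring_constant(*e) for e in net.edges}
        apply_perturbation(net, PerturbationSpec.mutation(3, "up", 5.0), model)
        assert {e: net.spring_constant(*e) for e in net.edges} == before

    def test_edge_set_superset_of_input(self, dimer24):
        model, _ = dimer24
        net = build_contact_network(model)
        site = SiteDefinition("s", ("A:1", "B:1", "A:5"))
        spec = PerturbationSpec(
            (
                PerturbationAction(PerturbationKind.BINDING, site, 10.0),
                PerturbationAction(PerturbationKind.DOWN, "A:3", 0.1),
            )
        )
        out = apply_perturbation(net, spec, model)
        assert set(net.edges).issubset(set(out.edges))

    def test_actions_compose_multiplicatively_on_shared_edges(self, helix30):
        model, _ = helix30
        net = build_contact_network(model)
        spec = PerturbationSpec(
            (
                PerturbationAction(PerturbationKind.UP, "A:10", 2.0),
                PerturbationAction(PerturbationKind.UP, "A:11", 3.0),
            )
        )
        out = apply_perturbation(net, spec, model)
        i, j = model.index_of("A:10"), model.index_of("A:11")
        assert out.spring_constant(i, j) == pytest.approx(6.0)


class TestSiteCombinations:
    def test_four_sites_choose_two_gives_six_labeled_pairs(self):
        sites = [SiteDefinition(f"ADPa.{i}", (f"A:{i}",), symmetry_group="ADPa")
                 for i in (1, 2, 3, 4)]
        specs = enumerate_site_combinations(sites, 2)
        labels = [s.actions[0].targets.label for s in specs]
        assert labels == [
            "ADPa.1 & ADPa.2",
            "ADPa.1 & ADPa.3",
            "ADPa.1 & ADPa.4",
            "ADPa.2 & ADPa.3",
            "ADPa.2 & ADPa.4",
            "ADPa.3 & ADPa.4",
        ]

    def test_choose_all_and_choose_one(self):
        sites = [SiteDefinition(f"S.{i}", (f"A:{i}",), symmetry_group="S")
                 for i in range(1, 5)]
        assert len(enumerate_site_combinations(sites, 4)) == 1
        assert len(enumerate_site_combinations(sites, 1)) == 4

    @given(n=st.integers(1, 8), data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_count_matches_binomial(self, n, data):
        k = data.draw(st.integers(1, n))
        sites = [SiteDefinition(f"S.{i}", (f"A:{i}",), symmetry_group="S")
                 for i in range(n)]
        assert len(enumerate_site_combinations(sites, k)) == math.comb(n, k)

    def test_choose_out_of_range_raises(self):
        sites = [SiteDefinition("S.1", ("A:1",), symmetry_group="S")]
        with pytest.raises(ValidationError):
            enumerate_site_combinations(sites, 0)
        with pytest.raises(ValidationError):
            enumerate_site_combinations(sites, 2)


class TestSiteInput:
    def test_parse_site_string(self, dimer24):
        model, _ = dimer24
        site = parse_site_string("iface", "A:1,A:2,B:1")
        assert site.resolve(model) == [0, 1, 12]

    def test_load_sites_json(self):
        text = """
        {"sites": [
          {"label": "ADPa.1", "members": ["A:1", {"chain": "A", "resnum": 2}],
           "symmetry_group": "ADPa"},
          {"label": "ADPa.2", "members": ["B:1", "B:2"], "symmetry_group": "ADPa"}
        ]}
        """
        sites = load_sites_json(text)
        assert [s.label for s in sites] == ["ADPa.1", "ADPa.2"]
        assert sites[0].symmetry_group == "ADPa"
        assert sites[0].members[1] == ("A", 2, "")
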