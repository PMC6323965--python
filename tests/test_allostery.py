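"""The free-energy core: ε parameters, Δg, Δh, site modulation, range."""

import numpy as np
import pytest

from allokit import (
    FixtureSpec,
    PerturbationSpec,
    SiteDefinition,
    ValidationError,
    allosteric_potential_params,
    apply_perturbation,
    build_contact_network,
    delta_h_for_spec,
    epsilon_from_vectors,
    flag_extreme_residues,
    free_energy_profile,
    generate_fixture,
    modes_for,
    modulation_profile,
    modulation_range_profile,
    site_modulation,
)
from allokit.allostery import FreeEnergyProfile, ModulationProfile

from conftest import structure_from_coords
from oracle import naive_springs, neighbor_sets_from_springs, oracle_delta_g


class TestEpsilon:
    def test_translation_mode_gives_exact_zero(self, cluster5):
        model, _ = cluster5
        net = build_contact_network(model)
        t = np.tile(np.array([1.0, 2.0, -0.5]), (1, model.n_residues, 1))
        eps = epsilon_from_vectors(t, net)
        assert np.all(eps == 0.0)

    def test_two_bead_stretch_epsilon_is_one(self):
        # e = (u, -u)/sqrt(2), |u| = 1/sqrt(2): |e_1 - e_2|^2 = |2u/sqrt2|^2 = 1
        model = structure_from_coords([[0, 0, 0], [5, 0, 0]])
        net = build_contact_network(model, cutoff=11.0)
        u = np.array([1.0, 0.0, 0.0]) / np.sqrt(2.0)
        mode = np.stack([u, -u]) / np.sqrt(2.0)
        eps = epsilon_from_vectors(mode[None], net)
        np.testing.assert_allclose(eps, [[1.0, 1.0]], atol=1e-14)

    def test_matches_naive_triple_loop(self, cluster5):
        from oracle import naive_epsilon

        model, _ = cluster5
        net = build_contact_network(model)
        modes = modes_for(model, net)
        eps = epsilon_from_vectors(modes.nonrigid_vectors, net)
        neighbor_sets = [net.neighbors(i) for i in range(model.n_residues)]
        np.testing.assert_allclose(
            eps, naive_epsilon(modes.nonrigid_vectors, neighbor_sets), atol=1e-12
        )

    def test_epsilon_nonnegative(self, helix_model):
        assert np.all(helix_model.params0.epsilon >= 0)

    def test_invariant_under_uniform_spring_scaling(self, cluster5):
        model, _ = cluster5
        net1 = build_contact_network(model, base_k=1.0)
        net2 = build_contact_network(model, base_k=2.0)
        p1 = allosteric_potential_params(modes_for(model, net1), net1)
        p2 = allosteric_potential_params(modes_for(model, net2), net1)
        np.testing.assert_allclose(p1.epsilon, p2.epsilon, atol=1e-8)


class TestFreeEnergy:
    def test_null_perturbation_is_exactly_zero(self, helix_model):
        fe = free_energy_profile(helix_model.params0, helix_model.params0)
        assert np.all(fe.delta_g == 0.0)

    def test_uniform_spring_doubling_gives_zero(self, helix30):
        model, _ = helix30
        net0 = build_contact_network(model, base_k=1.0)
        net2 = build_contact_network(model, base_k=2.0)
        p0 = allosteric_potential_params(modes_for(model, net0), net0)
        p2 = allosteric_potential_params(modes_for(model, net2), net0)
        fe = free_energy_profile(p0, p2)
        assert np.abs(fe.delta_g).max() < 1e-8

    def test_mode_count_mismatch_raises(self, helix_model, cluster5):
        model, _ = cluster5
        net = build_contact_network(model)
        p_small = allosteric_potential_params(modes_for(model, net), net)
        with pytest.raises(ValidationError):
            free_energy_profile(helix_model.params0, p_small)

    @pytest.mark.parametrize("fixture_name,mutated,alpha,kind",
                             [("cluster4", 0, 10.0, "up"),
                              ("cluster5", 2, 10.0, "up"),
                              ("cluster5", 1, 0.1, "down")])
    def test_matches_quadrature_oracle(self, fixture_name, mutated, alpha, kind,
                                       request):
        """Δg agrees with per-mode Gaussian-normalization quadrature."""
        model, _ = request.getfixturevalue(fixture_name)
        net = build_contact_network(model)
        spec = PerturbationSpec.mutation(mutated, kind, alpha)
        fe, _ = delta_h_for_spec(model, net, spec)

        springs0 = naive_springs(model.coords)
        springs_p = dict(springs0)
        for e in springs_p:
            if mutated in e:
                springs_p[e] = springs_p[e] * alpha
        neighbor_sets = neighbor_sets_from_springs(springs0, model.n_residues)
        expected = oracle_delta_g(model.coords, springs0, springs_p, neighbor_sets)
        np.testing.assert_allclose(fe.delta_g, expected, atol=1e-6)


class TestModulation:
    def test_constant_delta_g_gives_zero(self):
        fe = FreeEnergyProfile(delta_g=np.full(7, 3.3))
        mod = modulation_profile(fe, np.array(["A"] * 7))
        assert np.abs(mod.delta_h).max() < 1e-14

    def test_arithmetic_one_chain(self):
        fe = FreeEnergyProfile(delta_g=np.array([1.0, 2.0, 3.0]))
        mod = modulation_profile(fe, np.array(["A"] * 3))
        np.testing.assert_allclose(mod.delta_h, [-1.0, 0.0, 1.0], atol=1e-14)

    def test_per_chain_mean_zero(self):
        rng = np.random.default_rng(0)
        chains = np.array(["A"] * 10 + ["B"] * 15)
        fe = FreeEnergyProfile(delta_g=rng.normal(size=25))
        mod = modulation_profile(fe, chains)
        for c in "AB":
            assert abs(mod.delta_h[chains == c].mean()) < 1e-10

    def test_global_scope(self):
        fe = FreeEnergyProfile(delta_g=np.array([1.0, 2.0, 3.0, 10.0]))
        mod = modulation_profile(fe, np.array(["A", "A", "B", "B"]), scope="global")
        assert abs(mod.delta_h.mean()) < 1e-12
        assert mod.delta_h[0] == pytest.approx(1.0 - 4.0)


class TestSiteModulation:
    def test_whole_chain_site_averages_to_zero(self, helix_model):
        res = helix_model.fit_mutation("A:5", "up")
        site = SiteDefinition("all", tuple(helix_model.structure.labels))
        sm = res.site_modulation(site)
        assert abs(sm.delta_h_site) < 1e-10

    def test_single_residue_site(self, helix_model):
        res = helix_model.fit_mutation("A:5", "up")
        sm = res.site_modulation(SiteDefinition("one", ("A:17",)))
        assert sm.delta_h_site == pytest.approx(float(res.delta_h[16]))

    def test_two_residue_mean(self):
        mod = ModulationProfile(delta_h=np.array([1.0, -3.0, 2.0]))
        model = structure_from_coords([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        sm = site_modulation(mod, SiteDefinition("s", ("A:1", "A:2")), model)
        assert sm.delta_h_site == pytest.approx(-1.0)


class TestModulationRange:
    def test_equal_alphas_give_zero_range(self):
        h = np.array([0.5, -0.2, -0.3])
        rng = modulation_range_profile(ModulationProfile(h), ModulationProfile(h.copy()))
        assert np.all(rng.delta_h == 0.0)

    def test_identity_range_plus_down_equals_up(self, helix_model):
        up = helix_model.fit_mutation("A:12", "up").modulation
        down = helix_model.fit_mutation("A:12", "down").modulation
        rng = modulation_range_profile(up, down)
        np.testing.assert_array_equal(rng.delta_h + down.delta_h, up.delta_h)

    def test_range_mean_zero_per_chain(self, dimer24):
        model, _ = dimer24
        net = build_contact_network(model)
        _, up = delta_h_for_spec(model, net, PerturbationSpec.mutation("B:3", "up"))
        _, down = delta_h_for_spec(model, net, PerturbationSpec.mutation("B:3", "down"))
        rng = modulation_range_profile(up, down)
        for c in "AB":
            assert abs(rng.delta_h[model.chain_ids == c].mean()) < 1e-10


class TestFlagging:
    def test_all_zero_profile_flags_nothing(self):
        high, low = flag_extreme_residues(ModulationProfile(np.zeros(5)))
        assert high == [] and low == []

    def test_absolute_threshold_arithmetic(self):
        mod = ModulationProfile(np.array([-2.0, 0.0, 2.0]))
        high, low = flag_extreme_residues(mod, threshold=1.0, rule="absolute")
        assert high == [2] and low == [0]

    @pytest.mark.parametrize("rule,threshold", [("std", 1.0), ("absolute", 0.3),
                                                ("quantile", 0.8)])
    def test_high_low_disjoint(self, helix_model, rule, threshold):
        res = helix_model.fit_mutation("A:20", "up")
        high, low = flag_extreme_residues(res.modulation, threshold, rule)
        assert not set(high) & set(low)
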