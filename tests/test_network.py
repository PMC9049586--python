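"""Structure of the life-cycle network, mass-action rate laws and the ODE
right-hand side, checked against an independently hand-written oracle."""

from __future__ import annotations

import numpy as np
import pytest

from pkclife.network import (
    MOIETY_COUNTS,
    Parameterization,
    SPECIES_NAMES,
    build_default_network,
    conserved_moiety_total,
    initial_state,
    mass_action_flux,
)


def reference_rhs(y, p, act, k3_eff, k17_eff, hsp70, variant=False):
    """Hand-written derivative equations, species by species — the oracle
    the stoichiometry-matrix RHS must reproduce.  The direct degradation
    of the membrane-active form (lam5) exists only in the variant."""
    (mrna, c1, pkc, c2, pa, cpa, c3, c4, m, astar, d, c5) = y
    v1f = p.k1 * mrna * p.T
    v1r = p.k2 * c1
    v2 = k3_eff * c1
    v3 = p.lam1 * pkc
    v4f = p.k4 * pkc * p.PDK1
    v4r = p.k5 * c2
    v4c = p.k6 * c2
    v5f = p.k7 * pa * p.MTORC2
    v5r = p.k8 * cpa
    v6 = p.lam2 * pa
    v7f = p.k9 * cpa ** 2
    v7r = p.k10 * c3
    v7c = p.k11 * c3
    v8f = p.k12 * m * cpa
    v8r = p.k13 * c4
    v8c = p.k14 * c4
    v9f = p.k15 * act * m
    v9r = p.k16 * astar
    v10 = k17_eff * astar
    v11 = p.lam3 * d
    v12f = p.k18 * m * hsp70 * d
    v12r = p.k19 * c5
    v12c = p.k20 * c5
    vm = p.lam4 * m
    vma = p.lam5 * astar if variant else 0.0
    return np.array([
        -v1f + v1r + v2,                                   # PKC_mRNA
        v1f - v1r - v2,                                    # C1
        v2 - v3 - v4f + v4r,                               # PKC
        v4f - v4r - v4c,                                   # C2
        v4c - v5f + v5r - v6,                              # PKC_PA
        v5f - v5r - 2 * v7f + 2 * v7r + v7c - v8f + v8r,   # CPKC_PA
        v7f - v7r - v7c,                                   # C3
        v8f - v8r - v8c,                                   # C4
        v7c + 2 * v8c - v8f + v8r - v9f + v9r
        - v12f + v12r + 2 * v12c - vm,                     # CPKC_PAPHPT
        v9f - v9r - v10 - vma,                             # PKC_PAPHPT_act
        v10 - v11 - v12f + v12r,                           # PKC_A
        v12f - v12r - v12c,                                # C5
    ])


def _random_params(rng) -> Parameterization:
    d = {f"k{i}": 10 ** rng.uniform(-4, 0) for i in range(1, 21)}
    d.update({f"lam{i}": 10 ** rng.uniform(-5, -2) for i in range(1, 6)})
    d.update(T=rng.uniform(0.5, 2), PDK1=rng.uniform(0.5, 2),
             MTORC2=rng.uniform(0.5, 2), PHLPP=1.0,
             HSP70=rng.uniform(0.5, 2), mRNA0=1.0)
    return Parameterization.from_dict(d)


class TestStructure:
    def test_counts(self, network):
        assert len(network.reactions) == 13
        assert len(network.dynamical_species) == 12
        assert len(network.clamped_species) == 6
        assert {s.name for s in network.clamped_species} == {
            "T", "PDK1", "MTORC2", "ACT", "PHLPP", "HSP70"}

    def test_variant_adds_one_reaction(self):
        var = build_default_network(variant=True)
        assert len(var.reactions) == 14
        assert var.reactions[-1].id == "RMA"

    def test_every_rate_constant_resolves(self, network, params):
        for pid in network.rate_constant_ids:
            assert params.get(pid) >= 0

    def test_moiety_counts(self, network):
        by_name = {s.name: s for s in network.dynamical_species}
        assert by_name["C1"].pkc_moiety_count == 0
        assert by_name["PKC_mRNA"].pkc_moiety_count == 0
        for c in ("C3", "C4", "C5"):
            assert by_name[c].pkc_moiety_count == 2

    @pytest.mark.parametrize("rid,delta", [
        ("R1", 0), ("R2", 1), ("R3", -1), ("R4", 0), ("R5", 0),
        ("R6", -1), ("R7", 0), ("R8", 0), ("R9", 0), ("R10", 0),
        ("R11", -1), ("R12", 0), ("RM", -1),
    ])
    def test_moiety_delta(self, network, rid, delta):
        assert network.moiety_delta(rid) == delta

    def test_variant_degradation_delta(self):
        var = build_default_network(variant=True)
        assert var.moiety_delta("RMA") == -1


class TestParameterization:
    def test_negative_value_rejected(self, params):
        with pytest.raises(ValueError, match="lam1"):
            params.with_(lam1=-1.0)

    def test_unknown_id_rejected(self, params):
        with pytest.raises(KeyError):
            params.get("k99")
        with pytest.raises(KeyError):
            Parameterization.from_dict({**params.to_dict(), "bogus": 1.0})

    def test_roundtrip(self, params):
        assert Parameterization.from_dict(params.to_dict()) == params


class TestMassActionFlux:
    def test_first_order_decay_flux(self, network, params):
        state = {"PKC": 50.0}
        flux = mass_action_flux(network.step("R3"), state, params)
        assert flux == pytest.approx(50.0 * params.lam1)
        assert flux == pytest.approx(0.05)

    def test_zero_state_gives_zero_flux(self, network, params):
        y = np.zeros(12)
        for step in network.steps:
            assert mass_action_flux(step, y, params) == 0.0

    def test_no_activator_no_activation(self, network, params):
        state = {"CPKC_PAPHPT": 10.0}
        flux = mass_action_flux(network.step("R9f"), state, params,
                                clamped_levels={"ACT": 0.0})
        assert flux == 0.0
        flux = mass_action_flux(network.step("R9f"), state, params,
                                clamped_levels={"ACT": 0.5})
        assert flux == pytest.approx(params.k15 * 0.5 * 10.0)


class TestRhsOracle:
    """The generic stoichiometry-matrix RHS must equal the hand-written
    species-by-species equations to machine precision."""

    @pytest.mark.parametrize("variant", [False, True])
    def test_matrix_rhs_equals_reference(self, rng, variant):
        net = build_default_network(variant=variant)
        for _ in range(100):
            p = _random_params(rng)
            y = rng.uniform(0, 50, size=12)
            act, k3e, k17e, hsp = (rng.uniform(0, 0.5), p.k3,
                                   p.k17, p.HSP70)
            rates = net.rate_vector(p, k3_eff=k3e, k17_eff=k17e,
                                    act=act, hsp70=hsp)
            got = net.rhs_from_rates(rates, y)
            want = reference_rhs(y, p, act, k3e, k17e, hsp, variant)
            np.testing.assert_allclose(got, want, rtol=1e-13, atol=1e-15)

    @pytest.mark.parametrize("variant", [False, True])
    def test_moiety_weighted_derivative_identity(self, rng, variant):
        """Sum of moiety-weighted derivatives telescopes to synthesis
        minus the degradation fluxes: every internal conversion cancels."""
        net = build_default_network(variant=variant)
        for _ in range(50):
            p = _random_params(rng)
            y = rng.uniform(0, 50, size=12)
            rates = net.rate_vector(p, k3_eff=p.k3, k17_eff=p.k17,
                                    act=0.3, hsp70=p.HSP70)
            dy = net.rhs_from_rates(rates, y)
            got = float(MOIETY_COUNTS @ dy)
            idx = {n: i for i, n in enumerate(SPECIES_NAMES)}
            want = (p.k3 * y[idx["C1"]]
                    - p.lam1 * y[idx["PKC"]]
                    - p.lam2 * y[idx["PKC_PA"]]
                    - p.lam4 * y[idx["CPKC_PAPHPT"]]
                    - p.lam3 * y[idx["PKC_A"]])
            if variant:
                want -= p.lam5 * y[idx["PKC_PAPHPT_act"]]
            # the identity is a cancellation of O(|dy|) internal fluxes,
            # so "machine precision" is relative to the flux scale
            scale = float(np.sum(np.abs(dy)))
            assert abs(got - want) <= 1e-12 * max(scale, 1.0)

    def test_jacobian_matches_finite_differences(self, rng, network):
        p = _random_params(rng)
        y = rng.uniform(0.1, 20, size=12)
        rates = network.rate_vector(p, act=0.2)
        jac = network.jacobian_from_rates(rates, y)
        eps = 1e-7
        for i in range(12):
            dy = np.zeros(12)
            dy[i] = eps * max(1.0, y[i])
            num = (network.rhs_from_rates(rates, y + dy)
                   - network.rhs_from_rates(rates, y - dy)) / (2 * dy[i])
            np.testing.assert_allclose(jac[:, i], num, rtol=5e-6, atol=1e-8)


class TestMoietyTotal:
    def test_zero_state(self):
        assert conserved_moiety_total(np.zeros(12)) == 0.0

    def test_dimer_complex_counts_twice(self):
        y = np.zeros(12)
        y[SPECIES_NAMES.index("C3")] = 5.0
        assert conserved_moiety_total(y) == 10.0

    def test_initial_state_is_basal(self, params):
        y0 = initial_state(params)
        assert conserved_moiety_total(y0) == 0.0
        assert y0[SPECIES_NAMES.index("PKC_mRNA")] == params.mRNA0


def test_network_serialization_roundtrip(network):
    doc = network.to_dict()
    assert len(doc["reactions"]) == 13
    assert len(doc["species"]) == 18
    ids = [r["id"] for r in doc["reactions"]]
    assert ids[0] == "R1" and ids[-1] == "RM"
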