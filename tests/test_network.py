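"""Structural and rate-law tests of the EGFR-ERK reaction network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egfr_erk.network import (
    MIG6_PARAMETERS,
    ModelVariant,
    ParameterSet,
    RateLaw,
    Reaction,
    build_reference_network,
    conservation_pools,
    make_variant,
    rate,
    receptor_pool_weights,
)

MM_STEPS = {4, 11} | set(range(15, 28))


class TestStructure:
    def test_declared_model_size(self, network):
        assert len(network.reactions) == 27
        assert len(network.species) == 29
        assert len(network.dynamic_species_ids) == 27  # one ODE per dynamic state

    def test_step_indices_cover_1_to_27(self, network):
        assert [r.step_index for r in network.reactions] == list(range(1, 28))

    def test_michaelis_menten_exactly_on_declared_steps(self, network):
        mm = {
            r.step_index
            for r in network.reactions
            if r.law is RateLaw.MICHAELIS_MENTEN
        }
        assert mm == MM_STEPS

    def test_every_reaction_parameter_exists(self, network):
        for r in network.reactions:
            for pname in r.parameters.values():
                assert pname in network.parameters

    def test_frozen_system_has_zero_derivatives(self, network):
        # all rate constants driven to (numerical) zero freeze every state
        frozen = ParameterSet(
            {k: 1e-300 for k in network.parameters.values}
        )
        from egfr_erk.simulate import build_rhs

        rhs = build_rhs(network.with_parameters(frozen), frozen)
        y0 = np.array(
            [s.initial_concentration for s in network.species]
        )
        y0[0] = 10.0  # EGF present; still no flux without rate constants
        assert np.max(np.abs(rhs(0.0, y0))) < 1e-250


class TestRateLaws:
    def test_mm_half_saturation_identity(self, network):
        r4 = network.reactions[3]
        Km = network.parameters["Km4"]
        V = network.parameters["V4"]
        state = {sid: 0.0 for sid in network.species_ids}
        state["E11P"] = Km
        assert rate(r4, state, network.parameters) == pytest.approx(V / 2)

    def test_mm_nine_km_gives_090_vmax(self, network):
        r4 = network.reactions[3]
        Km = network.parameters["Km4"]
        V = network.parameters["V4"]
        state = {sid: 0.0 for sid in network.species_ids}
        state["E11P"] = 9 * Km
        assert rate(r4, state, network.parameters) == pytest.approx(0.9 * V)

    def test_mass_action_zero_reactant_zero_forward(self, network):
        r5 = network.reactions[4]  # E11P + Cbl binding
        state = {sid: 0.0 for sid in network.species_ids}
        state["Cbl"] = 85.0  # E11P absent
        assert rate(r5, state, network.parameters) == 0.0

    def test_catalyzed_mm_scales_with_modifier(self, network):
        r20 = network.reactions[19]
        state = {sid: 0.0 for sid in network.species_ids}
        state["MEK"] = 120.0
        state["Raf1A"] = 10.0
        v1 = rate(r20, state, network.parameters)
        state["Raf1A"] = 20.0
        assert rate(r20, state, network.parameters) == pytest.approx(2 * v1)

    def test_mm_to_mass_action_limit(self, network):
        # Km -> inf at fixed V/Km approaches first-order mass action
        r4 = network.reactions[3]
        slope = 7.0
        state = {sid: 0.0 for sid in network.species_ids}
        for Km in (1e6, 1e9):
            params = network.parameters.updated({"V4": slope * Km, "Km4": Km})
            S = Km / 100.0 * 1e-4
            state["E11P"] = S
            flux = rate(r4, state, params)
            assert flux == pytest.approx(slope * S, rel=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        conc=st.lists(
            st.floats(0, 1e4, allow_nan=False), min_size=29, max_size=29
        )
    )
    def test_rate_finite_for_nonnegative_states(self, conc):
        net = build_reference_network()
        state = dict(zip(net.species_ids, conc))
        for r in net.reactions:
            assert np.isfinite(rate(r, state, net.parameters))


class TestConservationStructure:
    def test_expected_pools_present(self, network):
        pools = dict(conservation_pools(network))
        assert pools["MEK"] == {"MEK", "MEKP", "MEKPP"}
        assert pools["ERK"] == {"ERK", "ERKP", "ERKPP"}
        assert "EGFR" not in pools and "receptor" not in pools

    def test_pool_indicators_annihilate_stoichiometry(self, network):
        # left-null-space oracle: each pool's indicator vector kills S
        S = network.stoichiometry_matrix()
        for name, ids in conservation_pools(network):
            w = np.zeros(len(network.species))
            for sid in ids:
                w[network.index_of(sid)] = 1.0
            assert np.max(np.abs(w @ S)) == 0.0, name

    def test_receptor_weights_annihilate_stoichiometry(self, network):
        S = network.stoichiometry_matrix()
        weights = receptor_pool_weights(network)
        w = np.zeros(len(network.species))
        for sid, wt in weights.items():
            w[network.index_of(sid)] = wt
        assert np.max(np.abs(w @ S)) == 0.0


class TestVariants:
    def test_wt_is_identity(self, network):
        v = make_variant("WT", network, {})
        assert v.initial_overrides == {}
        assert v.parameter_multipliers == {}
        assert v.effective_parameters() == network.parameters

    def test_l858r_a_multiplies_exactly_four_parameters(self, network):
        v = make_variant("L858R_A", network)
        assert set(v.parameter_multipliers) == set(MIG6_PARAMETERS)
        base = network.parameters
        eff = v.effective_parameters()
        changed = {
            n for n in base.values if base[n] != eff[n]
        }
        assert changed == set(MIG6_PARAMETERS)

    def test_l858r_b_shares_parameters_raises_cbl(self, network):
        b = make_variant("L858R_B", network)
        egfr_wt = make_variant("EGFR_WT", network)
        assert b.effective_parameters() == egfr_wt.effective_parameters()
        base_cbl = dict(
            (s.id, s.initial_concentration) for s in network.species
        )["Cbl"]
        assert b.initial_overrides["Cbl"] > base_cbl

    def test_unknown_variant_rejected(self, network):
        with pytest.raises(ValueError, match="unknown variant"):
            make_variant("T790M", network)

    def test_mig6_multipliers_must_slow(self, network):
        with pytest.raises(ValueError, match="slowed"):
            make_variant(
                "L858R_A",
                network,
                {"multipliers": {"k3": 1.5, "k5": 0.5, "k7": 0.5, "k8": 0.5}},
            )

    def test_negative_concentration_rejected(self, network):
        with pytest.raises(ValueError):
            make_variant("EGFR_WT", network, {"EGFR": -5.0})

    def test_variant_isolation(self, network):
        before = dict(network.parameters.values)
        v = make_variant("L858R_A", network)
        v.effective_parameters()
        from egfr_erk.simulate import StimulusProtocol, simulate

        simulate(v, StimulusProtocol(egf_dose=10.0, t_outputs=(0.0, 5.0)))
        assert network.parameters.values == before


class TestParameterSet:
    def test_value_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            ParameterSet({"k": 5.0}, {"k": (0.1, 1.0)})

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ParameterSet({"k": 0.0})

    def test_scaled_requires_known_parameter(self, network):
        with pytest.raises(KeyError):
            network.parameters.scaled({"nonexistent": 0.5})
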