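"""Gefitinib scans, R-ratio indices, inversion and synergy classification."""

import numpy as np
import pytest

from egfr_erk.network import DEFAULT_VARIANT_SETTINGS, ModelVariant
from egfr_erk.perturbation import (
    ALPHA_ON,
    DOWNSTREAM_READOUTS,
    MIG6_PAIRS,
    InversionError,
    PerturbationSpec,
    alpha_scan,
    classify_combination,
    downstream_amplification,
    inhibition_percent,
    invert_inhibition,
    pairwise_index_grid,
    r_index,
)
from egfr_erk.simulate import StimulusProtocol, observable_values, simulate

L858R_A_MULT = DEFAULT_VARIANT_SETTINGS["L858R_A"]["multipliers"]


class TestAlphaScan:
    def test_no_drug_point_normalizes_to_one(self, variants):
        scan = alpha_scan(variants["EGFR_WT"], alphas=(1.0, 0.1))
        for p, v in scan.items():
            assert v[0] == pytest.approx(1.0)

    def test_pegfr_vanishes_as_alpha_goes_to_zero(self, variants):
        scan = alpha_scan(variants["EGFR_WT"], alphas=(1.0, 1e-6))
        assert scan["pEGFR"][-1] < 0.01

    def test_pegfr_nondecreasing_in_alpha(self, variants):
        alphas = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0)
        scan = alpha_scan(variants["EGFR_WT"], alphas=alphas)
        assert np.all(np.diff(scan["pEGFR"]) >= -1e-9)

    def test_alpha_outside_unit_interval_rejected(self, variants):
        with pytest.raises(ValueError):
            alpha_scan(variants["EGFR_WT"], alphas=(1.0, 1.5))


class TestRIndex:
    def test_equal_alphas_give_unit_index(self):
        assert r_index("pERK", alpha_on=0.5, alpha_off=0.5) == pytest.approx(1.0)

    def test_matches_independent_recomputation(self, variants):
        # oracle: two hand-rolled simulations instead of the cached pair
        idx = r_index("pShc", context=PerturbationSpec())
        vals = {}
        for a in (ALPHA_ON, 1.0):
            traj = simulate(
                variants["EGFR_WT"],
                StimulusProtocol(egf_dose=10.0, gefitinib_alpha=a,
                                 t_outputs=(0.0, 5.0)),
            )
            vals[a] = observable_values(traj, "pShc")[-1]
        assert idx == pytest.approx(vals[ALPHA_ON] / vals[1.0], rel=1e-9)

    def test_six_mig6_pairs_enumerated(self):
        assert MIG6_PAIRS == (
            ("k3", "k5"), ("k3", "k7"), ("k3", "k8"),
            ("k5", "k7"), ("k5", "k8"), ("k7", "k8"),
        )

    def test_grid_corner_at_unit_factors_is_egfr_wt_index(self):
        grid = pairwise_index_grid(("k3", "k5"), grids=((1.0,), (1.0,)))
        expected = (
            r_index("pShc", context=PerturbationSpec())
            / r_index("pERK", context=PerturbationSpec())
        )
        assert grid.matrix[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_fitted_corner_recovers_full_l858r_a_index(self):
        fixed = {"k5": L858R_A_MULT["k5"], "k7": L858R_A_MULT["k7"]}
        grid = pairwise_index_grid(
            ("k3", "k8"),
            grids=((L858R_A_MULT["k3"],), (L858R_A_MULT["k8"],)),
            fixed=fixed,
        )
        ctx = PerturbationSpec(multipliers=dict(L858R_A_MULT))
        expected = (
            r_index("pShc", context=ctx) / r_index("pERK", context=ctx)
        )
        assert grid.matrix[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_l858r_a_index_far_exceeds_egfr_wt(self):
        ctx_a = PerturbationSpec(multipliers=dict(L858R_A_MULT))
        idx_a = r_index("pShc", context=ctx_a) / r_index("pERK", context=ctx_a)
        idx_w = (
            r_index("pShc", context=PerturbationSpec())
            / r_index("pERK", context=PerturbationSpec())
        )
        assert idx_a >= 5.0 * idx_w

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            pairwise_index_grid(("k3", "k3"))
        with pytest.raises(ValueError):
            pairwise_index_grid(("k3", "kcat20"))


@pytest.fixture(scope="module")
def corner():
    # single-point grids at the fitted L858R_A factors
    return downstream_amplification(
        k3_grid=(L858R_A_MULT["k3"],), k8_grid=(L858R_A_MULT["k8"],)
    )


class TestDownstreamAmplification:

    def test_readout_list(self, corner):
        assert tuple(corner) == DOWNSTREAM_READOUTS

    def test_mapk_steps_amplify_more_than_ras_raf(self, corner):
        vals = {y: corner[y].matrix[0, 0] for y in corner}
        assert min(vals["MEKPP"], vals["ERKP"], vals["ERKPP"]) > max(
            vals["RasGTP"], vals["Raf1A"]
        )

    def test_erkpp_amplifies_beyond_rasgtp(self, corner):
        assert corner["ERKPP"].matrix[0, 0] > corner["RasGTP"].matrix[0, 0]

    def test_unit_corner_equals_egfr_wt_baseline(self):
        # definitional corner: factor (1, 1) is the unperturbed EGFR-WT model
        res = downstream_amplification(k3_grid=(1.0,), k8_grid=(1.0,))
        ctx = PerturbationSpec()
        r_up = r_index("E11P_ShcP_GS", context=ctx)
        for y, r in res.items():
            expected = r_up / r_index(y, context=ctx)
            assert r.matrix[0, 0] == pytest.approx(expected, rel=1e-6), y


class TestInversion:
    def test_zero_target_returns_unit_factor(self):
        assert invert_inhibition("k3", 0.0) == (1.0, 0.0)

    @pytest.mark.parametrize("parameter", ["k3", "k8"])
    def test_round_trip(self, parameter):
        target = 5.0
        factor, achieved = invert_inhibition(parameter, target)
        assert factor < 1.0  # inhibition requires slowing
        redone = inhibition_percent({parameter: factor})
        assert abs(redone - target) < 0.1

    def test_unreachable_target_raises(self):
        with pytest.raises(InversionError, match="achievable range"):
            invert_inhibition("k3", 99.9999, log10_range=(-1.0, 0.0))

    def test_multiplier_order_is_immaterial(self, network):
        p = StimulusProtocol(egf_dose=10.0, t_outputs=(0.0, 5.0))
        v1 = ModelVariant("EGFR_WT", network, {"EGFR": 700.0},
                          {"k3": 0.01, "k8": 0.02})
        v2 = ModelVariant("EGFR_WT", network, {"EGFR": 700.0},
                          {"k8": 0.02, "k3": 0.01})
        t1, t2 = simulate(v1, p), simulate(v2, p)
        np.testing.assert_array_equal(t1.states, t2.states)


@pytest.fixture(scope="module")
def synergy_result():
    return classify_combination(X_grid=(0, 10, 40))


class TestSynergy:

    def test_zero_intensity_is_exactly_additive(self, synergy_result):
        row = synergy_result.rows[0]
        assert row.k3_factor == 1.0 and row.k8_factor == 1.0
        assert row.combined_inhibition == pytest.approx(0.0, abs=1e-9)
        assert row.classification == "additive"

    def test_combined_perturbations_act_synergistically(self, synergy_result):
        for row in synergy_result.rows[1:]:
            assert row.classification == "synergistic"
            assert row.combined_inhibition > row.X

    def test_classification_stable_across_epsilon(self, synergy_result):
        for eps in (0.25, 0.5, 1.0):
            for row in synergy_result.rows:
                margin = row.combined_inhibition - row.X
                if abs(margin) > 1.0:
                    cls = (
                        "synergistic" if margin > eps
                        else "antagonistic" if margin < -eps
                        else "additive"
                    )
                    assert cls == row.classification
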