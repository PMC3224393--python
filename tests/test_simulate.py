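"""Simulation, observable and normalization tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from egfr_erk.network import conservation_pools, receptor_pool_weights
from egfr_erk.simulate import (
    DEFAULT_TIME_GRID,
    PHOSPHO_PROTEINS,
    ObservableSeries,
    SolverConfig,
    StimulusProtocol,
    Trajectory,
    build_rhs,
    dose_response,
    normalize_panel,
    observable_values,
    observables,
    rhs_reference,
    simulate,
)


class TestSimulate:
    def test_zero_stimulus_keeps_phospho_silent(self, variants):
        traj = simulate(variants["EGFR_WT"], StimulusProtocol(egf_dose=0.0))
        for p in PHOSPHO_PROTEINS:
            assert np.max(np.abs(observable_values(traj, p))) < 1e-9

    def test_unstimulated_state_is_stationary(self, network):
        rhs = build_rhs(network, network.parameters)
        y0 = np.array([s.initial_concentration for s in network.species])
        assert np.max(np.abs(rhs(0.0, y0))) < 1e-12

    def test_egf_bath_not_depleted(self, trajectories_10nM):
        for traj in trajectories_10nM.values():
            assert np.allclose(traj["EGF"], 10.0, rtol=0, atol=1e-9)

    def test_pegfr_peaks_at_10min_in_egfr_wt_panel_wide(self, trajectories_10nM):
        # the pEGFR panel maximum is EGFR-WT at t = 10 min
        best = max(
            (
                (float(observable_values(traj, "pEGFR")[i]), name, t)
                for name, traj in trajectories_10nM.items()
                for i, t in enumerate(traj.times)
            )
        )
        _, cell, t_peak = best
        assert cell == "EGFR_WT"
        assert t_peak == 10.0

    def test_solver_tolerance_convergence(self, variants):
        proto = StimulusProtocol(egf_dose=10.0, t_outputs=(0.0, 5.0))
        coarse = simulate(variants["EGFR_WT"], proto, SolverConfig())
        fine = simulate(
            variants["EGFR_WT"], proto, SolverConfig(rtol=0.5e-8, atol=0.5e-12)
        )
        a = observable_values(coarse, "ERKPP")[-1]
        b = observable_values(fine, "ERKPP")[-1]
        assert abs(a - b) / b < 1e-4

    def test_states_stay_nonnegative(self, trajectories_10nM):
        atol = SolverConfig().atol
        for traj in trajectories_10nM.values():
            assert traj.states.min() >= -atol

    def test_rejects_bad_protocols(self):
        with pytest.raises(ValueError):
            StimulusProtocol(egf_dose=-1.0)
        with pytest.raises(ValueError):
            StimulusProtocol(gefitinib_alpha=0.0)
        with pytest.raises(ValueError):
            StimulusProtocol(t_outputs=(1.0, 5.0))  # missing t = 0


class TestConservation:
    def test_pools_closed_along_trajectories(self, network, trajectories_10nM):
        for traj in trajectories_10nM.values():
            for name, ids in conservation_pools(network):
                total = sum(traj[sid] for sid in ids)
                drift = np.max(np.abs(total - total[0])) / total[0]
                assert drift <= 1e-6, (traj.variant, name)

    def test_receptor_mass_plus_sink_constant(self, network, trajectories_10nM):
        weights = receptor_pool_weights(network)
        for traj in trajectories_10nM.values():
            total = sum(w * traj[sid] for sid, w in weights.items())
            assert np.max(np.abs(total - total[0])) / total[0] <= 1e-6


class TestRHS:
    def test_codegen_matches_reference_interpreter(self, network, rng):
        rhs = build_rhs(network, network.parameters)
        for _ in range(20):
            y = rng.uniform(0.0, 200.0, len(network.species_ids))
            state = dict(zip(network.species_ids, y))
            ref = rhs_reference(network, network.parameters, state)
            got = rhs(0.0, y)
            expected = np.array([ref[sid] for sid in network.species_ids])
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_finite_differences_match_rhs(self, variants, network):
        # central differences of a densely sampled trajectory reproduce dx/dt
        h = 1e-3
        times = tuple(np.concatenate([[0.0], np.arange(2 - h, 8.0, h)]))
        traj = simulate(
            variants["EGFR_WT"], StimulusProtocol(egf_dose=10.0, t_outputs=times)
        )
        rhs = build_rhs(network, network.parameters)
        for k in range(2, len(times) - 1, 500):
            dx = (traj.states[:, k + 1] - traj.states[:, k - 1]) / (2 * h)
            f = rhs(traj.times[k], traj.states[:, k])
            scale = np.maximum(np.abs(f), 1e-3 * np.max(np.abs(f)))
            assert np.max(np.abs(dx - f) / scale) < 1e-3


class TestObservables:
    def _toy_trajectory(self, network, **levels):
        states = np.zeros((len(network.species), 2))
        for sid, v in levels.items():
            states[network.index_of(sid), :] = v
        return Trajectory(
            times=np.array([0.0, 5.0]),
            states=states,
            species_ids=tuple(network.species_ids),
            variant="WT",
            protocol=StimulusProtocol(t_outputs=(0.0, 5.0)),
        )

    def test_pshc_reduces_to_free_shcp_without_complexes(self, network):
        traj = self._toy_trajectory(network, ShcP=3.0)
        assert observable_values(traj, "pShc")[-1] == pytest.approx(3.0)

    def test_pmek_is_sum_of_phosphoforms(self, network):
        traj = self._toy_trajectory(network, MEKP=0.2, MEKPP=0.5)
        assert observable_values(traj, "pMEK")[-1] == pytest.approx(0.7)

    def test_pshc_dominates_free_shcp_in_simulation(self, trajectories_10nM):
        traj = trajectories_10nM["EGFR_WT"]
        assert np.all(
            observable_values(traj, "pShc") >= traj["ShcP"] - 1e-12
        )

    def test_unknown_observable_rejected(self, trajectories_10nM):
        with pytest.raises(KeyError):
            observable_values(trajectories_10nM["WT"], "pAKT")


class TestNormalizePanel:
    def _series(self, protein, values, variant="WT"):
        return ObservableSeries(
            protein=protein,
            times=np.arange(float(len(values))),
            values=np.asarray(values, dtype=float),
            variant=variant,
        )

    def test_forced_by_definition(self):
        out = normalize_panel(
            [self._series("pERK", [0, 2, 4], "A"), self._series("pERK", [0, 1, 2], "B")]
        )
        np.testing.assert_allclose(out[0].values, [0, 0.5, 1.0])
        np.testing.assert_allclose(out[1].values, [0, 0.25, 0.5])

    def test_all_zero_panel_stays_zero(self):
        out = normalize_panel([self._series("pERK", [0, 0, 0])])
        np.testing.assert_array_equal(out[0].values, [0, 0, 0])

    def test_t0_offset_is_subtracted(self):
        out = normalize_panel([self._series("pERK", [1.0, 2.0, 3.0])])
        np.testing.assert_allclose(out[0].values, [0, 0.5, 1.0])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_panel([])

    def test_exactly_one_series_attains_the_maximum(self, trajectories_10nM):
        panel = []
        for traj in trajectories_10nM.values():
            panel.extend(observables(traj))
        out = normalize_panel(panel)
        for protein in PHOSPHO_PROTEINS:
            tops = [
                s.variant
                for s in out
                if s.protein == protein and np.max(s.values) == 1.0
            ]
            assert len(tops) == 1, protein

    @settings(derandomize=True, max_examples=40)
    @given(
        panels=st.lists(
            st.lists(
                st.floats(0, 1e3, allow_nan=False), min_size=3, max_size=3
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_output_always_in_unit_interval(self, panels):
        series = [
            ObservableSeries(
                protein="pERK",
                times=np.array([0.0, 1.0, 2.0]),
                values=np.asarray(v),
                variant=str(i),
            )
            for i, v in enumerate(panels)
        ]
        out = normalize_panel(series)
        for s in out:
            assert s.values[0] == 0.0
            assert np.max(s.values) <= 1.0 + 1e-12


class TestDoseResponse:
    def test_zero_dose_silent(self, variants):
        dr = dose_response(variants["EGFR_WT"], [0.0])
        for p, v in dr.items():
            assert abs(v[0]) < 1e-9

    def test_pegfr_increases_with_dose(self, variants):
        dr = dose_response(variants["EGFR_WT"], [0.1, 10.0])
        assert dr["pEGFR"][1] >= dr["pEGFR"][0]

    def test_negative_dose_rejected(self, variants):
        with pytest.raises(ValueError):
            dose_response(variants["EGFR_WT"], [-1.0])
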