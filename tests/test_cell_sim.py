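"""Paced cell-model simulation: determinism, physiology, drug scaling."""

import numpy as np
import pytest

from tdprisk import ap_metrics, cell_sim
from tdprisk.drug_response import CHANNELS, NO_BLOCK, HillParams


class TestConfig:
    def test_grid_divisibility_enforced(self):
        with pytest.raises(ValueError):
            cell_sim.CellModelConfig(dt_ms=0.3)  # does not divide 2 ms
        with pytest.raises(ValueError):
            cell_sim.CellModelConfig(record_dt_ms=3.0)  # does not divide CL

    def test_scale_bounds_enforced(self):
        with pytest.raises(ValueError):
            cell_sim.CellModelConfig(drug_scales={"IKr": 1.5})
        with pytest.raises(ValueError):
            cell_sim.CellModelConfig(drug_scales={"bogus": 0.5})

    def test_samples_per_beat_default(self):
        assert cell_sim.CellModelConfig().samples_per_beat == 1000


class TestRhs:
    def test_neutral_scales_match_drug_free(self, steady_state):
        neutral = cell_sim.CellModelConfig(
            drug_scales={ch: 1.0 for ch in CHANNELS})
        default = cell_sim.CellModelConfig()
        dy1 = cell_sim.ord_rhs(steady_state, 100.0, neutral)
        dy2 = cell_sim.ord_rhs(steady_state, 100.0, default)
        assert np.array_equal(dy1, dy2)

    def test_full_ikr_block_zeroes_ikr_current(self, steady_state):
        cfg = cell_sim.CellModelConfig(drug_scales={"IKr": 0.0})
        cur = cell_sim.ord_currents(steady_state, 100.0, cfg)
        assert cur["IKr"] == 0.0
        # other currents unaffected by the IKr scale
        ref = cell_sim.ord_currents(steady_state, 100.0,
                                    cell_sim.CellModelConfig())
        assert cur["IK1"] == pytest.approx(ref["IK1"])

    def test_steady_state_residual_small(self, steady_state):
        """At the converged drug-free state with no stimulus the membrane
        potential is nearly stationary."""
        dy = cell_sim.ord_rhs(steady_state, 1000.0, cell_sim.CellModelConfig())
        assert abs(dy[0]) < 1e-2  # mV/ms


class TestRunToSteady:
    def test_zero_beats_returns_published_initial(self):
        state, norms = cell_sim.run_to_steady(n_beats=0)
        assert np.array_equal(state.values,
                              cell_sim.CellState.published_initial().values)
        assert len(norms) == 0

    def test_requires_drug_free(self):
        cfg = cell_sim.CellModelConfig(drug_scales={"IKr": 0.5})
        with pytest.raises(ValueError):
            cell_sim.run_to_steady(cfg, n_beats=1)

    def test_convergence_norm_decreases(self):
        _, norms = cell_sim.run_to_steady(n_beats=200)
        assert norms[199 - 1] < norms[19]  # beat 200 vs beat 20

    def test_determinism(self):
        a, _ = cell_sim.run_to_steady(n_beats=3)
        b, _ = cell_sim.run_to_steady(n_beats=3)
        assert np.array_equal(a.values, b.values)


class TestSimulateDrug:
    def test_beat_shape_and_indexing(self, drug_free_series):
        assert drug_free_series.v.shape == (5, 1000)
        tr = drug_free_series.trace(5)
        assert tr.beat_index == 5
        with pytest.raises(IndexError):
            drug_free_series.trace(6)
        with pytest.raises(IndexError):
            drug_free_series.trace(0)

    def test_neutral_scale_bitwise_equivalence(self, steady_state):
        explicit = cell_sim.CellModelConfig(
            drug_scales={ch: 1.0 for ch in CHANNELS})
        a = cell_sim.simulate_drug(steady_state, explicit, n_beats=3)
        b = cell_sim.simulate_drug(steady_state, cell_sim.CellModelConfig(),
                                   n_beats=3)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.final_state.values, b.final_state.values)

    def test_state_invariants_hold_after_paced_run(self, drug_free_series):
        drug_free_series.final_state.validate()  # gates in [0,1], conc > 0

    def test_ikr_block_prolongs_apd(self, steady_state):
        cfg = cell_sim.CellModelConfig(drug_scales={"IKr": 0.5})
        blocked = cell_sim.simulate_drug(steady_state, cfg, n_beats=5)
        free = cell_sim.simulate_drug(steady_state, cell_sim.CellModelConfig(),
                                      n_beats=5)
        apd_b = ap_metrics.apd(blocked.trace(5), 0.9)
        apd_f = ap_metrics.apd(free.trace(5), 0.9)
        assert apd_b > apd_f + 20  # IKr block markedly delays repolarization


class TestPhysiology:
    def test_resting_potential_in_range(self, steady_state):
        assert -90.0 <= steady_state.v <= -85.0

    def test_drug_free_apd90_in_plausible_range(self, drug_free_series):
        apd90 = ap_metrics.apd(drug_free_series.trace(5), 0.9)
        # endocardial cell at CL 2000 ms with the CiPA conductance rescale
        assert 250.0 <= apd90 <= 350.0

    def test_beat_to_beat_uniformity_at_steady_state(self, drug_free_series):
        apds = [ap_metrics.apd(drug_free_series.trace(b), 0.9)
                for b in range(1, 6)]
        assert max(apds) - min(apds) < 1.0  # ms

    def test_dt_halving_changes_apd90_below_1ms(self, steady_state):
        coarse = cell_sim.simulate_drug(
            steady_state, cell_sim.CellModelConfig(dt_ms=0.1), n_beats=3)
        fine = cell_sim.simulate_drug(
            steady_state, cell_sim.CellModelConfig(dt_ms=0.05), n_beats=3)
        a = ap_metrics.apd(coarse.trace(3), 0.9)
        b = ap_metrics.apd(fine.trace(3), 0.9)
        assert abs(a - b) < 1.0


class TestDrugScales:
    def test_all_sentinels_give_neutral_scales(self):
        hill = {ch: NO_BLOCK for ch in CHANNELS}
        scales = cell_sim.drug_scales_from_samples(hill, cmax=1.0, multiple=4)
        assert all(s == 1.0 for s in scales.values())

    def test_half_block_at_matching_concentration(self):
        hill = {"IKr": HillParams(ic50=4.0, hill=1.7)}
        scales = cell_sim.drug_scales_from_samples(hill, cmax=2.0, multiple=2)
        assert scales["IKr"] == pytest.approx(0.5)
        assert all(scales[ch] == 1.0 for ch in CHANNELS if ch != "IKr")

    def test_scales_monotone_in_multiple(self):
        hill = {"IKr": HillParams(2.0, 1.0), "ICaL": HillParams(10.0, 2.0)}
        s1 = cell_sim.drug_scales_from_samples(hill, cmax=1.0, multiple=1)
        s4 = cell_sim.drug_scales_from_samples(hill, cmax=1.0, multiple=4)
        for ch in CHANNELS:
            assert s4[ch] <= s1[ch]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            cell_sim.drug_scales_from_samples({}, cmax=1.0, multiple=0)
        with pytest.raises(ValueError):
            cell_sim.drug_scales_from_samples({}, cmax=-1.0, multiple=1)


def test_steady_state_fixture_is_converged_under_continuation(steady_state):
    """Continuing the shipped fixture changes the per-beat state by little."""
    cfg = cell_sim.CellModelConfig()
    _, norms = _continue_norms(steady_state, cfg, n_beats=3)
    assert norms.max() < 1e-2


def _continue_norms(state, cfg, n_beats):
    from tdprisk.cell_sim import _pace
    _, snaps, final = _pace(state, cfg, n_beats, record=False)
    first = np.linalg.norm(snaps[0] - state.values)
    rest = np.linalg.norm(np.diff(snaps, axis=0), axis=1)
    return final, np.concatenate([[first], rest])
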