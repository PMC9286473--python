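import numpy as np
import pytest

from seapump.attenuation import SeasonalAttenuation
from seapump.ecosystem import (EcosystemParams, apply_ecosystem_step,
                               ecosystem_tendencies, sink_detritus)
from seapump.model_core import TRACER_NAMES, TracerState, total_phosphorus

PARAMS = EcosystemParams()
CONST_B = SeasonalAttenuation(b_ref=1.388, delta_b=0.0)


def _light(grid, value=200.0):
    return np.full(grid.cell_area.shape, value)


class TestEcosystemTendencies:
    def test_no_spontaneous_generation(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.PO4[small_grid.wet_mask] = 2.0
        tend = ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid)
        for name in TRACER_NAMES:
            assert np.allclose(tend[name], 0.0)

    def test_detritus_decay_rate(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.DET[small_grid.wet_mask] = 1.0
        tend = ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid)
        wet = small_grid.wet_mask
        assert np.allclose(tend["DET"][wet], -0.05)
        assert np.allclose(tend["PO4"][wet], +0.05)

    def test_budget_closes_per_cell(self, small_grid, rng):
        state = TracerState.zeros(small_grid)
        for name in TRACER_NAMES:
            getattr(state, name)[...] = rng.uniform(0, 2, small_grid.shape)
        tend = ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid)
        total = sum(tend[name] for name in TRACER_NAMES)
        assert np.max(np.abs(total)) < 1e-14

    def test_growth_confined_to_euphotic(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.PO4[small_grid.wet_mask] = 2.0
        state.PHY[small_grid.wet_mask] = 0.5
        tend = ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid)
        # below the euphotic zone PHY only loses mass
        deep = ~small_grid.euphotic_mask
        assert np.all(tend["PHY"][deep] <= 0)
        # in the euphotic zone with light and nutrient, net growth is positive
        assert tend["PO4"][0][small_grid.wet_mask[0]].max() < 0

    def test_negative_state_rejected(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.PO4[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid)

    def test_lambda_override_field(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.DET[small_grid.wet_mask] = 1.0
        lam = np.full(small_grid.shape, 0.1)
        tend = ecosystem_tendencies(state, _light(small_grid), PARAMS, small_grid,
                                    lambda_det=lam)
        assert np.allclose(tend["DET"][small_grid.wet_mask], -0.1)


class TestApplyEcosystemStep:
    def test_positivity_random_states(self, small_grid, rng):
        state = TracerState.zeros(small_grid)
        for name in TRACER_NAMES:
            getattr(state, name)[...] = rng.uniform(0, 5, small_grid.shape)
        for _ in range(20):
            state, _ = apply_ecosystem_step(state, _light(small_grid), PARAMS,
                                            small_grid, dt=0.5)
            for name in TRACER_NAMES:
                assert np.all(getattr(state, name)[small_grid.wet_mask] >= 0), name

    def test_conserves_phosphorus(self, small_grid, rng):
        state = TracerState.zeros(small_grid)
        for name in TRACER_NAMES:
            getattr(state, name)[...] = rng.uniform(0, 3, small_grid.shape)
        before = total_phosphorus(state, small_grid)
        for _ in range(100):
            state, _ = apply_ecosystem_step(state, _light(small_grid), PARAMS,
                                            small_grid, dt=0.5)
        after = total_phosphorus(state, small_grid)
        assert after == pytest.approx(before, rel=1e-12)

    def test_det_decay_is_exponential(self, small_grid):
        state = TracerState.zeros(small_grid)
        state.DET[small_grid.wet_mask] = 1.0
        dt = 0.5
        state, _ = apply_ecosystem_step(state, _light(small_grid) * 0.0, PARAMS,
                                        small_grid, dt=dt)
        wet = small_grid.wet_mask
        assert np.allclose(state.DET[wet], np.exp(-0.05 * dt), rtol=1e-12)


class TestSinkDetritus:
    def test_zero_detritus_zero_flux(self, small_grid):
        det = np.zeros(small_grid.shape)
        po4 = np.zeros(small_grid.shape)
        det2, po42, flux = sink_detritus(det, po4, 0.0, CONST_B, small_grid, 0.5)
        assert np.all(flux == 0)
        assert np.all(det2 == 0)

    def test_interface_mode_flux_at_120m(self, small_grid):
        # naive interface speed: F(120) = a * 120 * DET = 4.32 per unit conc.
        det = np.where(small_grid.wet_mask, 1.0, 0.0)
        po4 = np.zeros(small_grid.shape)
        _, _, flux = sink_detritus(det, po4, 0.0, CONST_B, small_grid, 0.5,
                                   mode="interface")
        k120 = small_grid.interface_index(120.0)
        wet_cols = small_grid.n_wet > 2
        assert flux[k120][wet_cols] == pytest.approx(4.32, abs=5e-3)

    def test_conserves_phosphorus_including_seafloor(self, small_grid, rng):
        state = TracerState.zeros(small_grid)
        state.DET[...] = rng.uniform(0, 2, small_grid.shape)
        state.DET[~small_grid.wet_mask] = 0.0
        before = total_phosphorus(state, small_grid)
        det, po4 = state.DET, state.PO4
        for it in range(200):
            det, po4, _ = sink_detritus(det, po4, 0.5 * it, CONST_B,
                                        small_grid, 0.5)
        state.DET, state.PO4 = det, po4
        assert total_phosphorus(state, small_grid) == pytest.approx(before, rel=1e-12)

    def test_positivity(self, small_grid, rng):
        det = np.where(small_grid.wet_mask, rng.uniform(0, 1, small_grid.shape), 0.0)
        po4 = np.zeros(small_grid.shape)
        fast = SeasonalAttenuation(b_ref=0.555, delta_b=0.0)  # fastest sinking
        for it in range(50):
            det, po4, _ = sink_detritus(det, po4, 0.5 * it, fast, small_grid, 0.5)
            assert det[small_grid.wet_mask].min() >= 0

    def test_steady_state_profile_is_martin(self, small_grid):
        """Column driven by a constant source converges to the power law."""
        lam, dt = 0.05, 0.5
        det = np.zeros(small_grid.shape)
        po4 = np.zeros(small_grid.shape)
        for it in range(30000):
            det[1] += 1.0 * dt              # production in layer 2 (50-120 m)
            det *= np.exp(-lam * dt)        # remineralization as in the model
            det, po4, flux = sink_detritus(det, po4, 0.0, CONST_B, small_grid, dt)
        f = flux[:, 0, 0]
        z = small_grid.interfaces
        expected = f[2] * (z[3:8] / 120.0) ** (-1.388)
        assert np.allclose(f[3:8], expected, rtol=1e-3)

    def test_negative_detritus_rejected(self, small_grid):
        det = np.zeros(small_grid.shape)
        det[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            sink_detritus(det, np.zeros(small_grid.shape), 0.0, CONST_B,
                          small_grid, 0.5)

    def test_unknown_mode_rejected(self, small_grid):
        det = np.zeros(small_grid.shape)
        with pytest.raises(ValueError):
            sink_detritus(det, det.copy(), 0.0, CONST_B, small_grid, 0.5,
                          mode="upstream")


def test_params_validation():
    with pytest.raises(ValueError):
        EcosystemParams(gamma_Z=1.5)
    with pytest.raises(ValueError):
        EcosystemParams(mu_max=-0.1)
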