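"""Brownian-dynamics simulator: limits, transport oracles, determinism.

Heavier ensemble checks (run-duration optima, speed saturation,
dt-halving at full scale) live in the acceptance suite; here the same
physics is verified at smaller problem sizes against closed-form
transport coefficients.
"""

import numpy as np
import pytest

from halotaxis import (
    ChemotaxisSimulation,
    SimConfig,
    chemotactic_efficiency,
    drift_velocity,
    ecoli_config,
    msd_along_gradient,
    simulate_ensemble,
)
from halotaxis.errors import ParameterError


class TestLimits:
    def test_straight_line_motion(self):
        """No noise, no reversals: displacement is exactly v0 t."""
        cfg = SimConfig(v_0=2.0, tau_run=1e6, D_r=0.0, D_t=0.0,
                        duration=50.0, n_cells=2, equilibration=0.0, seed=3)
        res = simulate_ensemble(cfg)
        d = np.linalg.norm(res.positions[-1] - res.positions[0], axis=1)
        np.testing.assert_allclose(d, 2.0 * res.times[-1], rtol=1e-9)

    def test_nonmotile_msd_is_diffusive(self):
        cfg = SimConfig(v_0=0.0, D_r=0.0, D_t=0.8, duration=200.0,
                        n_cells=150, equilibration=0.0, save_every=5, seed=4)
        res = simulate_ensemble(cfg)
        lags, ratio, alpha = res.msd(mode="lag")
        sel = (lags > 5) & (lags < 60)  # longest lags are sample-starved
        np.testing.assert_allclose(ratio[sel], 2 * 0.8, rtol=0.1)
        assert np.all(np.abs(alpha[sel]) < 0.35)

    def test_reversal_counts_match_poisson_rate(self):
        cfg = SimConfig(duration=1000.0, n_cells=50, seed=5)
        res = simulate_ensemble(cfg)
        expected = 1000.0 / 14.7
        tol = 3 * np.sqrt(expected) / np.sqrt(50)
        assert res.reversal_counts.mean() == pytest.approx(expected, abs=3 * tol)

    def test_invalid_discretization_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(tau_run=0.1, dt=0.033)


class TestTransportOracles:
    def test_direction_correlation_decay_rate(self):
        """mode=none: tangent correlation decays at 2 D_r + 2 lambda
        (reversals flip parity at Poisson rate; E[(-1)^N] = e^{-2 lambda t})."""
        cfg = SimConfig(v_0=2.0, tau_run=14.7, D_r=0.08, D_t=0.0,
                        duration=400.0, n_cells=100, save_every=5, seed=6)
        res = simulate_ensemble(cfg)
        pos = res.positions
        steps = np.diff(pos, axis=0)
        tang = steps / np.linalg.norm(steps, axis=2, keepdims=True)
        dt_s = res.times[1] - res.times[0]
        lags = np.arange(1, 25)
        corr = [
            np.mean(np.einsum("tij,tij->ti", tang[:-m], tang[m:]))
            for m in lags
        ]
        rate = -np.polyfit(lags * dt_s, np.log(corr), 1)[0]
        expected = 2 * 0.08 + 2 / 14.7
        assert rate == pytest.approx(expected, rel=0.10)

    def test_effective_diffusivity_green_kubo(self):
        """Long-time D_eff,x = v0^2 / (3 (2 D_r + 2 lambda))."""
        cfg = SimConfig(v_0=2.0, tau_run=14.7, D_r=0.08, D_t=0.0,
                        duration=800.0, n_cells=120, save_every=15, seed=7)
        res = simulate_ensemble(cfg)
        lags, ratio, _ = res.msd(mode="lag", n_lags=60)
        sel = (lags > 40) & (lags < 200)
        d_eff = np.mean(ratio[sel]) / 2
        expected = 4.0 / (3 * (0.16 + 2 / 14.7))
        assert d_eff == pytest.approx(expected, rel=0.15)

    def test_short_lag_ballistic_projection(self):
        """<x^2>/tau = (v0^2/3) tau at short lags (isotropic <cos^2> = 1/3)."""
        cfg = SimConfig(v_0=2.0, tau_run=1e5, D_r=0.0, D_t=0.0,
                        duration=60.0, n_cells=400, save_every=5, seed=8)
        res = simulate_ensemble(cfg)
        lags, ratio, _ = res.msd(mode="lag", n_lags=30)
        sel = lags < 3
        np.testing.assert_allclose(
            ratio[sel], (4.0 / 3) * lags[sel], rtol=0.10
        )

    def test_null_drift_consistent_with_zero(self):
        """mode=none: per-axis drift within 3 s.e. of zero (cell-level
        spread sets the honest error bar)."""
        cfg = SimConfig(duration=1000.0, n_cells=60, seed=9)
        res = simulate_ensemble(cfg)
        final = res.positions[-1]
        v_cells = final / res.times[-1]
        se = v_cells.std(axis=0, ddof=1) / np.sqrt(cfg.n_cells)
        assert np.all(np.abs(v_cells.mean(axis=0)) < 3 * se)


class TestChemotaxis:
    def test_bipolar_beats_single_sided_modes(self):
        """v_x(bipolar) >= v_x(lengthen), v_x(shorten) at matched
        parameters, within the sampling error."""
        drifts, ses = {}, {}
        for mode in ["bipolar", "lengthen", "shorten"]:
            cfg = SimConfig(duration=2000.0, n_cells=60,
                            response_mode=mode, seed=10)
            res = simulate_ensemble(cfg, seed=55)
            final_v = res.positions[-1, :, 0] / res.times[-1]
            drifts[mode] = final_v.mean()
            ses[mode] = final_v.std(ddof=1) / np.sqrt(cfg.n_cells)
        comb = 3 * np.hypot(ses["bipolar"], ses["lengthen"])
        assert drifts["bipolar"] >= drifts["lengthen"] - comb
        assert drifts["bipolar"] >= drifts["shorten"] - comb
        assert drifts["bipolar"] > 0

    def test_weak_response_linearity(self):
        """Doubling the response amplitude doubles v_x well below
        saturation (slope constant within the sampling tolerance)."""
        out = {}
        for beta in [0.2, 0.4]:
            cfg = SimConfig(duration=6000.0, n_cells=200,
                            response_mode="bipolar",
                            saturation_fraction=beta, seed=11)
            res = simulate_ensemble(cfg, seed=77)
            out[beta] = res.positions[-1, :, 0].mean() / res.times[-1]
        ratio = out[0.4] / out[0.2]
        assert ratio == pytest.approx(2.0, abs=0.4)

    def test_saturation_audit_small_at_calibrated_sensitivity(self):
        """With the calibrated W, the rate is essentially never floored."""
        cfg = SimConfig(duration=2000.0, n_cells=50, response_mode="bipolar",
                        seed=12)
        res = simulate_ensemble(cfg)
        assert res.floored_fraction < 0.01

    def test_ecoli_preset_tumbles(self):
        cfg = ecoli_config(duration=200.0, n_cells=20, response_mode="none")
        res = simulate_ensemble(cfg, seed=13)
        assert res.reversal_counts.mean() == pytest.approx(200.0, rel=0.3)


class TestObservables:
    def test_drift_velocity_exact_line(self):
        t = np.linspace(0, 100, 300)
        r = np.column_stack([0.2 * t, np.zeros_like(t), np.zeros_like(t)])
        v, se = drift_velocity(t, r)
        np.testing.assert_allclose(v, [0.2, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(se, 0.0, atol=1e-12)

    def test_drift_velocity_needs_points(self):
        with pytest.raises(ParameterError):
            drift_velocity(np.arange(5), np.zeros((5, 3)))

    def test_efficiency_algebra(self):
        out = chemotactic_efficiency(0.2, 2.0, 0.05)
        assert out["efficiency"] == pytest.approx(0.2 / (0.05 * 4.0))
        assert out["efficiency_gamma"] == pytest.approx(0.05)
        # doubling v0 at fixed v_x cuts eps*gamma fourfold
        out2 = chemotactic_efficiency(0.2, 4.0, 0.05)
        assert out2["efficiency_gamma"] == pytest.approx(0.05 / 4)
        with pytest.raises(ParameterError):
            chemotactic_efficiency(0.1, 0.0, 1.0)


class TestDeterminism:
    def test_identical_seed_identical_ensembles(self):
        cfg = SimConfig(duration=50.0, n_cells=5, response_mode="bipolar",
                        seed=21)
        a = simulate_ensemble(cfg)
        b = simulate_ensemble(cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.reversal_counts, b.reversal_counts)

    def test_different_seed_differs(self):
        cfg = SimConfig(duration=50.0, n_cells=5, seed=21)
        a = simulate_ensemble(cfg)
        b = simulate_ensemble(cfg, seed=22)
        assert not np.allclose(a.positions, b.positions)

    def test_isotropy_without_gradient(self):
        """mode=none: MSD along x, y, z statistically indistinguishable."""
        cfg = SimConfig(duration=600.0, n_cells=120, D_t=0.0, seed=23)
        res = simulate_ensemble(cfg)
        msds = []
        for axis in np.eye(3):
            lags, ratio, _ = msd_along_gradient(
                res.times, res.positions, axis, mode="lag", n_lags=20
            )
            sel = lags > 50
            msds.append(np.mean(ratio[sel]))
        msds = np.array(msds)
        assert msds.max() / msds.min() < 1.35
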