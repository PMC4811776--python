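"""Forward model: integrator oracles, hemodynamics, sampling, invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import two_node_params, two_node_timeline
from hierdcm.design import InputTimeline, design_from_blocks
from hierdcm.simulate import (
    DCMParameters,
    HemodynamicParams,
    ROITimeSeries,
    SimulationDivergedError,
    hemodynamic_response,
    integrate_neural,
    sample_bold,
    simulate_dataset,
)


def _impulse_timeline(n_steps: int, dt: float, kick_bins=(0,), n_regions: int = 1) -> InputTimeline:
    drive = np.zeros((n_steps, 1))
    for b in kick_bins:
        drive[b, 0] = 1.0
    return InputTimeline(dt=dt, drive=drive, mod=np.zeros((n_steps, 0)),
                         drive_names=("u1",), mod_names=())


class TestNeuralIntegration:
    def test_zero_input_zero_state(self):
        tl = _impulse_timeline(100, 0.125, kick_bins=())
        params = DCMParameters(("R1",), np.array([[-1.0]]), {}, np.zeros((1, 1)))
        traj = integrate_neural(params, tl)
        assert np.all(traj.x == 0.0)

    def test_matches_matrix_exponential_decay(self):
        """Free decay of A = diag(-1) follows the closed form e^{-t} x0."""
        dt = 0.125
        tl = _impulse_timeline(200, dt, kick_bins=())
        params = DCMParameters(("R1", "R2"), -np.eye(2), {}, np.zeros((2, 1)))
        x0 = np.array([1.0, 0.0])
        traj = integrate_neural(params, tl, x0=x0)
        t = np.arange(200) * dt
        expected = np.exp(-t)[:, None] * x0[None, :]
        assert np.max(np.abs(traj.x - expected)) < 1e-6

    def test_matches_piecewise_expm_with_kicks(self, rng):
        """Delta-driven 2-node system against exact propagation by expm."""
        dt = 0.25
        tl = two_node_timeline(rng, n_scans=20, dt=dt)
        params = two_node_params(0.3, 0.1)
        traj = integrate_neural(params, tl)
        E = expm(params.A * dt)
        x = np.zeros(2)
        worst = 0.0
        for t in range(tl.n_steps):
            x = x + params.C @ tl.drive[t]
            worst = max(worst, np.max(np.abs(x - traj.x[t])))
            x = E @ x
        assert worst < 1e-5

    def test_rk4_matches_fine_euler_with_modulation(self, rng):
        """Bilinear dynamics under a step modulation: RK4 at dt agrees with
        Euler at dt/100 (dt small enough that the oracle's own first-order
        error sits below the tolerance)."""
        dt = 0.01
        T = 1000
        A = np.array([[-0.6, 0.2], [0.15, -0.4]])
        B = np.array([[0.0, 0.2], [0.3, 0.0]])
        mod = np.zeros((T, 1))
        mod[T // 2 :, 0] = 1.0
        tl = InputTimeline(dt=dt, drive=np.zeros((T, 1)), mod=mod,
                           drive_names=("u1",), mod_names=("m1",))
        params = DCMParameters(("R1", "R2"), A, {"m1": B}, np.zeros((2, 1)))
        x0 = 0.5 * rng.standard_normal(2)
        traj = integrate_neural(params, tl, x0=x0)

        # independent fine-step Euler oracle
        sub = 100
        x = x0.copy()
        worst = 0.0
        for t in range(T):
            worst = max(worst, np.max(np.abs(x - traj.x[t])))
            M = A + mod[t, 0] * B
            for _ in range(sub):
                x = x + (dt / sub) * (M @ x)
        assert worst < 1e-5

    def test_linearity_and_superposition_in_C(self, rng):
        dt = 0.125
        tl1 = _impulse_timeline(400, dt, kick_bins=(0,))
        tl2 = _impulse_timeline(400, dt, kick_bins=(160,))
        tl12 = _impulse_timeline(400, dt, kick_bins=(0, 160))
        A = np.array([[-0.5, 0.2], [0.1, -0.5]])
        C = np.array([[1.0], [0.3]])
        p1 = DCMParameters(("R1", "R2"), A, {}, C)
        p3 = DCMParameters(("R1", "R2"), A, {}, 3.0 * C)
        xa = integrate_neural(p1, tl1).x
        assert np.allclose(integrate_neural(p3, tl1).x, 3.0 * xa, rtol=1e-8, atol=1e-12)
        xb = integrate_neural(p1, tl2).x
        xab = integrate_neural(p1, tl12).x
        assert np.allclose(xab, xa + xb, rtol=1e-8, atol=1e-12)

    def test_divergence_guard(self):
        tl = _impulse_timeline(4000, 0.125, kick_bins=(0,), n_regions=2)
        params = DCMParameters(("R1", "R2"), np.array([[-0.1, 2.0], [2.0, -0.1]]), {},
                               np.array([[1.0], [0.0]]))
        with pytest.raises(SimulationDivergedError):
            integrate_neural(params, tl)


class TestHemodynamics:
    def test_zero_neural_zero_bold(self):
        from hierdcm.simulate import StateTrajectory

        traj = StateTrajectory(dt=0.125, x=np.zeros((200, 2)), regions=("R1", "R2"))
        bold = hemodynamic_response(traj)
        assert np.allclose(bold.values, 0.0)

    def test_impulse_response_shape(self):
        """A brief neural impulse yields a single-peaked response with peak
        latency 3-8 s followed by an undershoot."""
        dt = 0.0625
        T = int(40 / dt)
        tl = _impulse_timeline(T, dt, kick_bins=(0,))
        params = DCMParameters(("R1",), np.array([[-1.0]]), {}, np.array([[1.0]]))
        traj = integrate_neural(params, tl)
        bold = hemodynamic_response(traj).values[:, 0]
        peak = int(np.argmax(bold))
        assert 3.0 <= peak * dt <= 8.0
        assert np.sum((np.diff(np.sign(np.diff(bold[: peak * 3]))) < 0)) == 1  # single peak early on
        assert bold[peak:].min() < 0  # undershoot

    def test_efficacy_scales_amplitude_to_first_order(self):
        dt = 0.125
        T = int(30 / dt)
        tl = _impulse_timeline(T, dt, kick_bins=(0,))
        params = DCMParameters(("R1",), np.array([[-1.0]]), {}, np.array([[0.01]]))
        traj = integrate_neural(params, tl)
        b1 = hemodynamic_response(traj, HemodynamicParams(epsilon=1.0)).values.max()
        b2 = hemodynamic_response(traj, HemodynamicParams(epsilon=2.0)).values.max()
        assert b2 / b1 == pytest.approx(2.0, rel=0.02)

    def test_invalid_hemo_params(self):
        with pytest.raises(ValueError):
            HemodynamicParams(tau=-1.0)
        with pytest.raises(ValueError):
            HemodynamicParams(alpha=1.5)


class TestSampling:
    def _bold(self, rng):
        tl = two_node_timeline(rng, n_scans=50, dt=0.125)
        params = two_node_params(0.2, 0.1)
        traj = integrate_neural(params, tl)
        return hemodynamic_response(traj)

    def test_noiseless_decimation(self, rng):
        bold = self._bold(rng)
        ts = sample_bold(bold, tr=2.0, noise_sd=0.0)
        assert np.array_equal(ts.data, bold.values[::16])

    def test_seed_reproducibility(self, rng):
        bold = self._bold(rng)
        a = sample_bold(bold, tr=2.0, noise_sd=0.5, seed=3)
        b = sample_bold(bold, tr=2.0, noise_sd=0.5, seed=3)
        c = sample_bold(bold, tr=2.0, noise_sd=0.5, seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_negative_noise_sd(self, rng):
        with pytest.raises(ValueError):
            sample_bold(self._bold(rng), noise_sd=-0.1)

    def test_ar1_autocorrelation(self):
        flat = InputTimeline(dt=2.0, drive=np.zeros((40000, 1)), mod=np.zeros((40000, 0)),
                             drive_names=("u1",), mod_names=())
        params = DCMParameters(("R1",), np.array([[-1.0]]), {}, np.zeros((1, 1)))
        bold = hemodynamic_response(integrate_neural(params, flat))
        ts = sample_bold(bold, tr=2.0, noise_sd=1.0, noise_model="ar1", ar_phi=0.3, seed=0)
        e = ts.data[:, 0]
        r1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert r1 == pytest.approx(0.3, abs=0.03)


class TestSimulateDataset:
    def test_zero_C_flat_noisy_baseline(self, small_design):
        params = DCMParameters(("R1",) * 1, np.array([[-0.5]]), {}, np.zeros((1, 3)))
        ts = simulate_dataset(params, design=small_design, noise_sd=0.1, seed=0)
        assert abs(ts.data.mean()) < 0.01
        assert ts.data.std() == pytest.approx(0.1, rel=0.05)

    def test_driven_region_dominates_variance(self, small_design):
        """With spatial input into SFS only, SFS variance exceeds FPl's."""
        from hierdcm.regions import REGIONS

        A = -0.5 * np.eye(6)
        C = np.zeros((6, 3))
        C[REGIONS.index("SFS"), 0] = 1.0
        params = DCMParameters(REGIONS, A, {}, C)
        ts = simulate_dataset(params, design=small_design, noise_sd=0.01, seed=1)
        var = ts.to_frame().var()
        assert var["SFS"] > 10 * var["FPl"]

    def test_step_halving_convergence(self, rng):
        tl = two_node_timeline(rng, n_scans=40, dt=0.125)
        params = two_node_params(0.25, 0.15)
        y1 = simulate_dataset(params, timeline=tl, noise_sd=0.0).data
        y2 = simulate_dataset(params, timeline=tl.resample(0.0625), noise_sd=0.0).data
        assert np.max(np.abs(y1 - y2)) < 1e-5

    def test_fixed_seed_byte_identical_csv(self, tmp_path, rng):
        tl = two_node_timeline(rng, n_scans=30, dt=0.125)
        params = two_node_params(0.2, 0.1)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_dataset(params, timeline=tl, noise_sd=0.2, seed=9).to_csv(p1)
        simulate_dataset(params, timeline=tl, noise_sd=0.2, seed=9).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_roundtrip(self, tmp_path, rng):
        tl = two_node_timeline(rng, n_scans=30, dt=0.125)
        ts = simulate_dataset(two_node_params(0.2, 0.1), timeline=tl, noise_sd=0.1, seed=2)
        path = tmp_path / "ts.csv"
        ts.to_csv(path)
        back = ROITimeSeries.from_csv(path)
        assert back.regions == ts.regions
        assert np.allclose(back.data, ts.data)
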