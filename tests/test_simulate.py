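"""Stochastic integrator: steady states, noise statistics, reproducibility."""

import numpy as np
import pytest

from transneuron.core import CircuitParams, DriveProtocol
from transneuron.potential import ConfigurationError
from transneuron.simulate import (
    SimConfig,
    Trace,
    enforce_boundaries_and_order,
    ramp_response,
    simulate,
    step,
)


class TestBoundaries:
    def test_single_reflection(self, device):
        d = 0.03
        assert enforce_boundaries_and_order(0.5 + d, device)[0] == pytest.approx(0.5 - d)
        assert enforce_boundaries_and_order(-0.5 - d, device)[0] == pytest.approx(-0.5 + d)

    def test_relabelling(self, device):
        dev2 = device.replace(n_particles=2)
        out = enforce_boundaries_and_order([0.3, -0.1], dev2)
        np.testing.assert_allclose(out, [-0.1, 0.3])

    def test_large_excursion_fold_oracle(self, device):
        # brute-force fold: step inward by reflections until inside the gap
        def brute(x, half):
            while x > half or x < -half:
                if x > half:
                    x = 2 * half - x
                else:
                    x = -2 * half - x
            return x

        rng = np.random.default_rng(7)
        for x in rng.uniform(-5, 5, 200):
            got = enforce_boundaries_and_order(x, device)[0]
            assert got == pytest.approx(brute(x, 0.5), abs=1e-12)
            assert -0.5 <= got <= 0.5


class TestSteadyStates:
    def test_frozen_particle_voltage_divider(self, device, noiseless_circuit):
        # eta -> inf limit: V relaxes to V_ext R / (R + R_ext)
        V_ext, T0 = 0.8, 1e-6
        cfg = SimConfig(dt=5e-4, t_max=30.0, seed=0, record_stride=10,
                        freeze_particles=True,
                        initial_state=([-0.3], T0, 0.0))
        tr = simulate(device, noiseless_circuit, DriveProtocol.dc(V_ext, T0), cfg)
        from transneuron.core import resistance_one
        R = resistance_one(-0.3, device)
        expected = V_ext * R / (R + noiseless_circuit.R_ext)
        assert tr.V[-1] == pytest.approx(expected, rel=1e-4)

    def test_frozen_particle_temperature(self, device, noiseless_circuit):
        V_ext, T0 = 0.8, 1e-6
        cfg = SimConfig(dt=5e-4, t_max=80.0, seed=0, record_stride=10,
                        freeze_particles=True,
                        initial_state=([-0.3], T0, 0.0))
        tr = simulate(device, noiseless_circuit, DriveProtocol.dc(V_ext, T0), cfg)
        from transneuron.core import resistance_one
        R = resistance_one(-0.3, device)
        V_inf = V_ext * R / (R + noiseless_circuit.R_ext)
        expected = T0 + V_inf ** 2 / (device.C_th * R * device.kappa)
        assert tr.T[-1] == pytest.approx(expected, rel=1e-3)

    def test_ou_stationary_variance(self, harmonic_device, noiseless_circuit):
        # harmonic U (k = 1), q = 0, T clamped: Var(x) = k_B T0 / k
        T0 = 0.01
        cfg = SimConfig(dt=5e-3, t_max=20000.0, seed=3, record_stride=2,
                        clamp_temperature=True, initial_state=([0.0], T0, 0.0))
        tr = simulate(harmonic_device, noiseless_circuit,
                      DriveProtocol.dc(0.0, T0), cfg)
        burn = len(tr.t) // 10
        var = np.var(tr.x[burn:, 0])
        assert var == pytest.approx(T0, rel=0.02)


class TestReproducibility:
    def test_bit_identical_traces(self, device, circuit):
        cfg = SimConfig(dt=5e-4, t_max=50.0, seed=42, record_stride=10)
        a = simulate(device, circuit, DriveProtocol.dc(1.35, 1e-6), cfg)
        b = simulate(device, circuit, DriveProtocol.dc(1.35, 1e-6), cfg)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.T, b.T)

    def test_seed_changes_trace(self, device, circuit):
        base = dict(dt=5e-4, t_max=50.0, record_stride=10)
        a = simulate(device, circuit, DriveProtocol.dc(1.35, 1e-6),
                     SimConfig(seed=1, **base))
        b = simulate(device, circuit, DriveProtocol.dc(1.35, 1e-6),
                     SimConfig(seed=2, **base))
        assert not np.array_equal(a.x, b.x)

    def test_zero_noise_deterministic(self, device, noiseless_circuit):
        cfg = SimConfig(dt=5e-4, t_max=50.0, seed=1, record_stride=10,
                        clamp_temperature=True)
        a = simulate(device, noiseless_circuit, DriveProtocol.dc(1.35, 0.0), cfg)
        b = simulate(device, noiseless_circuit, DriveProtocol.dc(1.35, 0.0),
                     SimConfig(dt=5e-4, t_max=50.0, seed=99, record_stride=10,
                               clamp_temperature=True))
        np.testing.assert_array_equal(a.x, b.x)  # seed-independent when D = D_V = 0


class TestTraceInvariants:
    def test_confinement_and_positivity(self, device, circuit):
        tr = simulate(device, circuit, DriveProtocol.dc(2.3, 1e-6),
                      SimConfig(dt=5e-4, t_max=200.0, seed=5, record_stride=5))
        assert np.all(tr.x >= -0.5) and np.all(tr.x <= 0.5)
        assert np.all(tr.T > 0)
        assert np.all(np.diff(tr.t) > 0)

    def test_two_particle_ordering(self, device, circuit):
        dev2 = device.replace(n_particles=2)
        tr = simulate(dev2, circuit, DriveProtocol.dc(1.5, 1e-6),
                      SimConfig(dt=5e-4, t_max=100.0, seed=2, record_stride=5))
        assert np.all(tr.x[:, 0] <= tr.x[:, 1] + 1e-12)

    def test_quiescent_below_threshold(self, device, noiseless_circuit):
        # zero noise below the spiking threshold: V settles to DC division
        cfg = SimConfig(dt=5e-4, t_max=100.0, seed=0, record_stride=10,
                        clamp_temperature=True)
        tr = simulate(device, noiseless_circuit, DriveProtocol.dc(0.4, 0.0), cfg)
        tail = tr.V[-50:]
        assert np.std(tail) < 1e-6
        from transneuron.core import resistance_one
        R = resistance_one(tr.x[-1, 0], device)
        assert tail[-1] == pytest.approx(0.4 * R / (R + 1.0), rel=1e-3)


class TestStepOracle:
    def test_python_step_matches_kernel_noise_free(self, device, noiseless_circuit):
        rng = np.random.default_rng(0)
        protocol = DriveProtocol.dc(1.0, 0.0)
        dt = 5e-4
        state = (np.array([-0.35]), 0.0, 0.2)
        n = 400
        for k in range(n):
            x, T, V = step(state, k * dt, device, noiseless_circuit, protocol,
                           dt, rng)
            state = (x, 0.0, V)  # clamp T like the kernel run below
        cfg = SimConfig(dt=dt, t_max=n * dt, seed=0, record_stride=n,
                        clamp_temperature=True,
                        initial_state=([-0.35], 0.0, 0.2))
        tr = simulate(device, noiseless_circuit, protocol, cfg)
        assert tr.x[-1, 0] == pytest.approx(state[0][0], abs=1e-6)
        assert tr.V[-1] == pytest.approx(state[2], rel=1e-6)


class TestRampAndIO:
    def test_constant_ramp_reduces_to_dc(self, device, circuit):
        cfg = SimConfig(dt=5e-4, t_max=50.0, seed=7, record_stride=10)
        a = ramp_response(device, circuit, 1.0, 1.0, 50.0, cfg, T0=1e-6)
        b = simulate(device, circuit, DriveProtocol.dc(1.0, 1e-6), cfg)
        np.testing.assert_array_equal(a.x, b.x)

    def test_trace_round_trip(self, tmp_path, device, circuit):
        tr = simulate(device, circuit, DriveProtocol.dc(1.35, 1e-6),
                      SimConfig(dt=5e-4, t_max=20.0, seed=1, record_stride=10))
        path = tmp_path / "trace.csv"
        tr.save(path)
        back = Trace.load(path)
        np.testing.assert_allclose(back.x, tr.x, rtol=1e-12)
        np.testing.assert_allclose(back.I, tr.I, rtol=1e-12)
        assert back.meta["seed"] == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(dt=0.0)
        with pytest.raises(ConfigurationError):
            SimConfig(dt=1.0, t_max=0.5)
        with pytest.raises(ConfigurationError):
            SimConfig(record_stride=0)
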