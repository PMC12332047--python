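"""Euler-Maruyama integration of the stochastic neuron circuit.

State per time step: cluster positions x_i, device temperature T and the
voltage V across the memristor.  The update rules are

    dx_i = [(-dU/dx_i + s q V / L) / eta] dt + sqrt(2 k_B T / eta) dW_i
    dT   = [V^2 / (C_th R) - kappa (T - T0(t))] dt
    dV   = [V_ext(t) - (1 + R_ext / R) V] / tau dt + sqrt(D_V) / tau dW_V

with s the field-sign convention, R the instantaneous tunnelling
resistance, D = 2 k_B T the position diffusion constant (Ito convention:
T is taken at the current step) and tau = R_ext C.  Positions are
reflected at the gap walls +-L/2 and, for two particles, relabelled in
ascending order after every step.

The inner loop is compiled with numba; noise comes from numba's global
MT19937 stream seeded per run, so identical (config, params, protocol,
seed) give bit-identical traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .core import (
    CircuitParams,
    ConstantDrive,
    ConstantTemperature,
    DeviceParams,
    DriveProtocol,
    RampDrive,
    conductance,
    resistance,
)
from .potential import ConfigurationError


class IntegrationError(RuntimeError):
    """Raised when the state leaves the finite domain during integration."""


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt is the Euler-Maruyama step, t_max the duration, record_stride the
    output decimation.  freeze_particles holds x fixed (the eta -> inf
    limit); clamp_temperature pins T to T0(t) (removes the Joule
    feedback on the noise level).
    """

    dt: float = 5e-4
    t_max: float = 1000.0
    seed: int = 0
    record_stride: int = 10
    initial_state: Optional[Tuple] = None  # (x array-like, T, V)
    freeze_particles: bool = False
    clamp_temperature: bool = False

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigurationError("dt must be > 0")
        if not self.t_max > self.dt:
            raise ConfigurationError("t_max must exceed dt")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")


@dataclass
class Trace:
    """Time-sampled system state produced by :func:`simulate`."""

    t: np.ndarray
    x: np.ndarray          # (n_samples, n_particles)
    T: np.ndarray
    V: np.ndarray
    I: np.ndarray
    G_norm: np.ndarray
    v_ext: np.ndarray
    t_bath: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for name in ("T", "V", "I", "G_norm", "v_ext", "t_bath"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"Trace.{name} length mismatch")
        if self.x.shape[0] != n:
            raise ValueError("Trace.x length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("Trace.t must be strictly increasing")

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i in range(self.x.shape[1]):
            cols[f"x{i + 1}"] = self.x[:, i]
        cols.update(T=self.T, V=self.V, I=self.I, G_norm=self.G_norm,
                    V_ext=self.v_ext, T0=self.t_bath)
        return pd.DataFrame(cols)

    def save(self, path_csv, path_meta=None) -> None:
        """Columnar CSV plus JSON sidecar with run provenance."""
        self.to_frame().to_csv(path_csv, index=False)
        if path_meta is None:
            path_meta = str(path_csv) + ".json"
        with open(path_meta, "w") as fh:
            json.dump(self.meta, fh, indent=1, default=float)

    @classmethod
    def load(cls, path_csv, path_meta=None) -> "Trace":
        df = pd.read_csv(path_csv)
        xcols = sorted(c for c in df.columns if c.startswith("x"))
        meta = {}
        if path_meta is None:
            path_meta = str(path_csv) + ".json"
        try:
            with open(path_meta) as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(
            t=df["t"].to_numpy(), x=df[xcols].to_numpy(),
            T=df["T"].to_numpy(), V=df["V"].to_numpy(), I=df["I"].to_numpy(),
            G_norm=df["G_norm"].to_numpy(), v_ext=df["V_ext"].to_numpy(),
            t_bath=df["T0"].to_numpy(), meta=meta,
        )


# ---------------------------------------------------------------------------
# reference python step (slow path; mirrors the compiled kernel)
# ---------------------------------------------------------------------------


def enforce_boundaries_and_order(x, params: DeviceParams):
    """Reflect positions into [-L/2, L/2] and sort ascending."""
    half = params.L / 2.0
    x = np.atleast_1d(np.asarray(x, dtype=float)).copy()
    span = 2.0 * half
    y = np.mod(x + half, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    x = y - half
    return np.sort(x)


def step(state, t, params: DeviceParams, circuit: CircuitParams,
         protocol: DriveProtocol, dt: float, rng: np.random.Generator):
    """One Euler-Maruyama update (x, T, V) -> (x, T, V).

    Reference implementation used in tests; :func:`simulate` runs the
    compiled equivalent.
    """
    x, T, V = state
    x = np.atleast_1d(np.asarray(x, dtype=float))
    R = resistance(x, params)
    v_ext = protocol.v_ext(t)
    t_bath = protocol.t_bath(t)
    sqdt = np.sqrt(dt)

    force = params.potential.force(x) + params.field_sign * params.q * V / params.L
    noise_x = np.sqrt(2.0 * params.k_B * max(T, 0.0) / params.eta) * rng.standard_normal(x.size)
    x_new = x + force / params.eta * dt + noise_x * sqdt
    x_new = enforce_boundaries_and_order(x_new, params)

    T_new = T + (V * V / (params.C_th * R) - params.kappa * (T - t_bath)) * dt
    tau = circuit.tau
    dV = (v_ext - (1.0 + circuit.R_ext / R) * V) / tau * dt
    dV += np.sqrt(circuit.D_V) / tau * sqdt * rng.standard_normal()
    if not (np.all(np.isfinite(x_new)) and np.isfinite(T_new) and np.isfinite(V + dV)):
        raise IntegrationError(f"non-finite state at t={t}: x={x_new}, T={T_new}, V={V + dV}")
    return x_new, T_new, V + dV


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _reflect(x, half):
    span = 2.0 * half
    y = (x + half) % (2.0 * span)
    if y < 0.0:
        y += 2.0 * span
    if y > span:
        y = 2.0 * span - y
    return y - half


@njit(cache=True)
def _kernel(x, T, V, n_steps, dt, stride,
            fgrid_x0, fgrid_dx, fgrid_F,
            R_t, lam, half, R0,
            sign_qL, eta, kB, Cth, kappa,
            R_ext, tau, sqrt_DV,
            vext, tbath, seed,
            freeze, clampT,
            out_x, out_T, out_V):
    np.random.seed(seed)
    n_p = x.size
    sqdt = np.sqrt(dt)
    nrec = 1
    out_T[0] = T
    out_V[0] = V
    for ip in range(n_p):
        out_x[0, ip] = x[ip]
    for k in range(n_steps):
        # resistance at current positions
        if n_p == 1:
            R = R0 * np.cosh(x[0] / lam)
        else:
            R = R_t * (np.exp((half + x[0]) / lam)
                       + np.exp((x[1] - x[0]) / lam)
                       + np.exp((half - x[1]) / lam))
        # positions
        if not freeze:
            Tpos = T if T > 0.0 else 0.0
            amp = np.sqrt(2.0 * kB * Tpos / eta) * sqdt
            for ip in range(n_p):
                xi = x[ip]
                # linear interpolation of -dU/dx on the dense grid
                u = (xi - fgrid_x0) / fgrid_dx
                j = int(u)
                if j < 0:
                    j = 0
                if j > fgrid_F.size - 2:
                    j = fgrid_F.size - 2
                w = u - j
                F = fgrid_F[j] * (1.0 - w) + fgrid_F[j + 1] * w
                F += sign_qL * V
                xi = xi + F / eta * dt + amp * np.random.normal()
                x[ip] = _reflect(xi, half)
            if n_p == 2 and x[0] > x[1]:
                tmp = x[0]
                x[0] = x[1]
                x[1] = tmp
        # temperature
        if clampT:
            T = tbath[k]
        else:
            T = T + (V * V / (Cth * R) - kappa * (T - tbath[k])) * dt
        # voltage
        V = V + (vext[k] - (1.0 + R_ext / R) * V) / tau * dt
        if sqrt_DV > 0.0:
            V = V + sqrt_DV / tau * sqdt * np.random.normal()
        if (k + 1) % stride == 0:
            if not (np.isfinite(V) and np.isfinite(T)):
                return -(k + 1)
            out_T[nrec] = T
            out_V[nrec] = V
            for ip in range(n_p):
                out_x[nrec, ip] = x[ip]
            nrec += 1
    return nrec


def _force_grid(params: DeviceParams, n: int = 8193):
    half = params.L / 2.0
    xg = np.linspace(-half, half, n)
    Fg = np.asarray(params.potential.force(xg), dtype=float)
    return xg[0], xg[1] - xg[0], Fg


def _default_initial_state(params: DeviceParams, circuit: CircuitParams,
                          protocol: DriveProtocol):
    x0 = np.full(params.n_particles, params.well_position, dtype=float)
    if params.n_particles == 2:
        x0[1] = min(params.well_position + 0.05 * params.L, params.L / 2)
    R = resistance(x0, params)
    V0 = protocol.v_ext(0.0) * R / (R + circuit.R_ext)
    T0 = protocol.t_bath(0.0)
    return x0, float(T0), float(V0)


def simulate(params: DeviceParams, circuit: CircuitParams,
             protocol: DriveProtocol, config: SimConfig) -> Trace:
    """Integrate the stochastic circuit and return a decimated Trace.

    The run is a deterministic function of (params, circuit, protocol,
    config.seed): re-running with identical inputs reproduces the trace
    bit for bit.
    """
    n_steps = int(round(config.t_max / config.dt))
    stride = config.record_stride
    if config.initial_state is not None:
        x0, T0, V0 = config.initial_state
        x0 = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
        if x0.size != params.n_particles:
            raise ConfigurationError("initial_state x size != n_particles")
    else:
        x0, T0, V0 = _default_initial_state(params, circuit, protocol)

    tgrid = np.arange(n_steps) * config.dt
    vext = np.asarray(protocol.v_ext(tgrid), dtype=float)
    tbath = np.asarray(protocol.t_bath(tgrid), dtype=float)
    if np.any(tbath < 0):
        raise ConfigurationError("bath temperature must be >= 0 at all times")

    n_rec = n_steps // stride + 1
    out_x = np.empty((n_rec, params.n_particles))
    out_T = np.empty(n_rec)
    out_V = np.empty(n_rec)

    gx0, gdx, gF = _force_grid(params)
    status = _kernel(
        x0.copy(), float(T0), float(V0), n_steps, config.dt, stride,
        gx0, gdx, gF,
        params.R_t, params.lambda_, params.L / 2.0, params.R0,
        params.field_sign * params.q / params.L,
        params.eta, params.k_B, params.C_th, params.kappa,
        circuit.R_ext, circuit.tau, float(np.sqrt(circuit.D_V)),
        vext, tbath, int(config.seed) & 0x7FFFFFFF,
        config.freeze_particles, config.clamp_temperature,
        out_x, out_T, out_V,
    )
    if status < 0:
        k = -status
        raise IntegrationError(
            f"non-finite state at t={k * config.dt:.6g} (step {k}); "
            "reduce dt or check parameters"
        )

    t = np.arange(n_rec) * (config.dt * stride)
    if params.n_particles == 1:
        R = params.R0 * np.cosh(out_x[:, 0] / params.lambda_)
        Rmin = params.R0
    else:
        half = params.L / 2.0
        lam = params.lambda_
        R = params.R_t * (np.exp((half + out_x[:, 0]) / lam)
                          + np.exp((out_x[:, 1] - out_x[:, 0]) / lam)
                          + np.exp((half - out_x[:, 1]) / lam))
        Rmin = params.R_t * (2.0 * np.exp(half / lam) + 1.0)
    I = out_V / R
    G_norm = Rmin / R

    v_ext_s = np.asarray(protocol.v_ext(t), dtype=float)
    t_bath_s = np.asarray(protocol.t_bath(t), dtype=float)
    meta = {
        "seed": int(config.seed), "dt": config.dt, "t_max": config.t_max,
        "record_stride": stride, "n_particles": params.n_particles,
    }
    return Trace(t=t, x=out_x, T=out_T, V=out_V, I=I, G_norm=G_norm,
                 v_ext=v_ext_s, t_bath=t_bath_s, meta=meta)


def ramp_response(params: DeviceParams, circuit: CircuitParams,
                  V_start: float, V_end: float, duration: float,
                  config: SimConfig, T0: float = None) -> Trace:
    """Simulate under a slow linear voltage ramp (regime / hysteresis scans)."""
    if T0 is None:
        T0 = 1e-4
    if V_start == V_end:
        voltage = ConstantDrive(V_start)
    else:
        voltage = RampDrive(V_start, V_end, duration)
    protocol = DriveProtocol(voltage, ConstantTemperature(T0))
    if config.t_max != duration:
        config = SimConfig(dt=config.dt, t_max=duration, seed=config.seed,
                           record_stride=config.record_stride,
                           initial_state=config.initial_state,
                           freeze_particles=config.freeze_particles,
                           clamp_temperature=config.clamp_temperature)
    return simulate(params, circuit, protocol, config)
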