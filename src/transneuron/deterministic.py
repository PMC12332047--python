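"""Noise-free thermophoretic model and its dynamical-systems analysis.

Thermal fluctuations are replaced by deterministic forces carried by the
thermal and electric gradients T' and V' in the gap, coupled to the
cluster through a thermal charge q_T (thermophoresis / Seebeck):

    eta dx/dt  = -dU/dx + s q V / L - q_T T'
    dT'/dt     = (2 V V' R - V^2 R') / (C_th R^2) - kappa T'
    tau dV/dt  = V_ext - (1 + R_ext / R) V
    tau dV'/dt = -(1 + R_ext / R) V' + (R_ext R' / R^2) V

(one mobile cluster; R = R(x), R' = dR/dx; s the field-sign convention
shared with the stochastic model).  The module finds fixed points and
their stability, continues branches over V_ext with Hopf detection,
scans for limit cycles by direct integration, runs adiabatic hysteresis
sweeps and classifies basins of attraction.

Fixed points are found by reducing the 4-D root problem to one dimension:
for frozen x the (T', V, V') subsystem is linear with closed-form steady
state

    V*  = V_ext R / (R + R_ext)
    V'* = (R'/R) (R_ext / (R + R_ext)) V*
    T'* = (2 V* V'* R - V*^2 R') / (C_th R^2 kappa)

so equilibria are roots of the scalar force balance
g(x) = -dU/dx + s q V*(x)/L - q_T T'*(x), bracketed on a grid and
refined with Brent's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import (
    CircuitParams,
    DeviceParams,
    resistance_one,
    resistance_gradient,
)

logger = logging.getLogger(__name__)

STABLE, UNSTABLE, SADDLE_FOCUS = "stable", "unstable", "saddle-focus"


@dataclass(frozen=True)
class DetState:
    """State of the deterministic model: (x, T', V, V')."""

    x: float
    T_prime: float
    V: float
    V_prime: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.T_prime, self.V, self.V_prime], dtype=float)

    @classmethod
    def from_array(cls, a) -> "DetState":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass(frozen=True)
class FixedPoint:
    state: DetState
    stability: str
    eigenvalues: np.ndarray


@dataclass
class BifurcationDiagram:
    """Fixed-point branches, Hopf points and limit-cycle extrema vs V_ext."""

    v_grid: np.ndarray
    fixed_points: pd.DataFrame      # columns: V_ext, x, stability, eig_real, eig_imag
    hopf_points: List[float]
    limit_cycles: pd.DataFrame      # columns: V_ext, x_min, x_max
    coexistence_windows: List[Tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: branch id, V_ext, x, kind, eigen-real, eigen-imag."""
        rows = []
        for _, r in self.fixed_points.iterrows():
            kind = "fp_stable" if r["stability"] == STABLE else "fp_unstable"
            rows.append(dict(branch="fp", V_ext=r["V_ext"], x=r["x"], kind=kind,
                             eig_real=r["eig_real"], eig_imag=r["eig_imag"]))
        for _, r in self.limit_cycles.iterrows():
            rows.append(dict(branch="lc", V_ext=r["V_ext"], x=r["x_min"],
                             kind="lc_min", eig_real=np.nan, eig_imag=np.nan))
            rows.append(dict(branch="lc", V_ext=r["V_ext"], x=r["x_max"],
                             kind="lc_max", eig_real=np.nan, eig_imag=np.nan))
        for v in self.hopf_points:
            rows.append(dict(branch="hopf", V_ext=v, x=np.nan, kind="hopf",
                             eig_real=0.0, eig_imag=np.nan))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def rhs(state, params: DeviceParams, circuit: CircuitParams, V_ext: float):
    """Time derivative of (x, T', V, V')."""
    if isinstance(state, DetState):
        x, Tp, V, Vp = state.x, state.T_prime, state.V, state.V_prime
    else:
        x, Tp, V, Vp = state
    R = resistance_one(x, params)
    Rp = resistance_gradient(x, params)
    tau = circuit.tau
    F = params.potential.force(x) + params.field_sign * params.q * V / params.L \
        - params.q_T * Tp
    dx = F / params.eta
    dTp = (2.0 * V * Vp * R - V * V * Rp) / (params.C_th * R * R) - params.kappa * Tp
    dV = (V_ext - (1.0 + circuit.R_ext / R) * V) / tau
    dVp = (-(1.0 + circuit.R_ext / R) * Vp + circuit.R_ext * Rp / (R * R) * V) / tau
    return np.array([float(dx), float(dTp), float(dV), float(dVp)])


def frozen_x_steady_state(x: float, params: DeviceParams, circuit: CircuitParams,
                          V_ext: float) -> DetState:
    """Closed-form steady state of the linear (T', V, V') subsystem at frozen x."""
    R = resistance_one(x, params)
    Rp = resistance_gradient(x, params)
    V = V_ext * R / (R + circuit.R_ext)
    Vp = (Rp / R) * (circuit.R_ext / (R + circuit.R_ext)) * V
    kappa = params.kappa
    if kappa == 0:
        Tp = 0.0 if abs(2 * V * Vp * R - V * V * Rp) < 1e-300 else np.inf
    else:
        Tp = (2.0 * V * Vp * R - V * V * Rp) / (params.C_th * R * R * kappa)
    return DetState(float(x), float(Tp), float(V), float(Vp))


def _force_balance(x: float, params, circuit, V_ext: float) -> float:
    st = frozen_x_steady_state(x, params, circuit, V_ext)
    return float(params.potential.force(x)
                 + params.field_sign * params.q * st.V / params.L
                 - params.q_T * st.T_prime)


def jacobian(state, params, circuit, V_ext, h: float = 1e-6) -> np.ndarray:
    """Jacobian of rhs by central finite differences."""
    s0 = state.as_array() if isinstance(state, DetState) else np.asarray(state, float)
    n = s0.size
    J = np.empty((n, n))
    for j in range(n):
        dp = s0.copy()
        dm = s0.copy()
        dp[j] += h
        dm[j] -= h
        J[:, j] = (rhs(dp, params, circuit, V_ext) - rhs(dm, params, circuit, V_ext)) / (2 * h)
    return J


def classify_stability(eigs: np.ndarray, tol: float = 1e-9) -> str:
    re = np.real(eigs)
    if np.all(re < -tol):
        return STABLE
    if np.any(np.abs(np.imag(eigs[re > tol])) > tol):
        return SADDLE_FOCUS if np.any(re < -tol) else UNSTABLE
    return UNSTABLE


def find_fixed_points(V_ext: float, params: DeviceParams, circuit: CircuitParams,
                      x_grid: Optional[np.ndarray] = None,
                      dedup_tol: float = 1e-6) -> List[FixedPoint]:
    """All equilibria of the deterministic model at a given V_ext.

    Roots of the scalar force balance are bracketed on ``x_grid`` (default
    2001 points over the gap interior) and refined by Brent's method, then
    tagged stable / unstable / saddle-focus from the Jacobian spectrum.
    """
    half = params.L / 2.0
    if x_grid is None:
        x_grid = np.linspace(-half * 0.999, half * 0.999, 2001)
    g = np.array([_force_balance(x, params, circuit, V_ext) for x in x_grid])
    roots: List[float] = []
    for i in np.nonzero(np.diff(np.sign(g)) != 0)[0]:
        try:
            r = brentq(_force_balance, x_grid[i], x_grid[i + 1],
                       args=(params, circuit, V_ext), xtol=1e-12)
        except ValueError:  # pragma: no cover - bracket lost to noise
            continue
        if not any(abs(r - r0) < dedup_tol for r0 in roots):
            roots.append(float(r))
    if not roots:
        logger.warning("no fixed points found at V_ext=%g", V_ext)
    out = []
    for r in sorted(roots):
        st = frozen_x_steady_state(r, params, circuit, V_ext)
        eigs = np.linalg.eigvals(jacobian(st, params, circuit, V_ext))
        out.append(FixedPoint(st, classify_stability(eigs), eigs))
    return out


# ---------------------------------------------------------------------------
# integration (fixed-step RK4 kernel + scipy cross-check path)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _det_rhs(x, Tp, V, Vp, V_ext,
             fx0, fdx, fF, R0, lam, qL, qT, eta, Cth, kappa, R_ext, tau, half):
    if x < -half:
        x = -half
    if x > half:
        x = half
    R = R0 * np.cosh(x / lam)
    Rp = (R0 / lam) * np.sinh(x / lam)
    u = (x - fx0) / fdx
    j = int(u)
    if j < 0:
        j = 0
    if j > fF.size - 2:
        j = fF.size - 2
    w = u - j
    F = fF[j] * (1.0 - w) + fF[j + 1] * w
    dx = (F + qL * V - qT * Tp) / eta
    dTp = (2.0 * V * Vp * R - V * V * Rp) / (Cth * R * R) - kappa * Tp
    dV = (V_ext - (1.0 + R_ext / R) * V) / tau
    dVp = (-(1.0 + R_ext / R) * Vp + R_ext * Rp / (R * R) * V) / tau
    return dx, dTp, dV, dVp


@njit(cache=True)
def _det_rk4(state, vext, dt, stride,
             fx0, fdx, fF, R0, lam, qL, qT, eta, Cth, kappa, R_ext, tau, half,
             out):
    x, Tp, V, Vp = state[0], state[1], state[2], state[3]
    n_steps = vext.size
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = x, Tp, V, Vp
    nrec = 1
    for k in range(n_steps):
        ve = vext[k]
        k1 = _det_rhs(x, Tp, V, Vp, ve, fx0, fdx, fF, R0, lam, qL, qT, eta,
                      Cth, kappa, R_ext, tau, half)
        k2 = _det_rhs(x + 0.5 * dt * k1[0], Tp + 0.5 * dt * k1[1],
                      V + 0.5 * dt * k1[2], Vp + 0.5 * dt * k1[3], ve,
                      fx0, fdx, fF, R0, lam, qL, qT, eta, Cth, kappa, R_ext, tau, half)
        k3 = _det_rhs(x + 0.5 * dt * k2[0], Tp + 0.5 * dt * k2[1],
                      V + 0.5 * dt * k2[2], Vp + 0.5 * dt * k2[3], ve,
                      fx0, fdx, fF, R0, lam, qL, qT, eta, Cth, kappa, R_ext, tau, half)
        k4 = _det_rhs(x + dt * k3[0], Tp + dt * k3[1],
                      V + dt * k3[2], Vp + dt * k3[3], ve,
                      fx0, fdx, fF, R0, lam, qL, qT, eta, Cth, kappa, R_ext, tau, half)
        x += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        Tp += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        V += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        Vp += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if x < -half:
            x = -half
        if x > half:
            x = half
        if (k + 1) % stride == 0:
            out[nrec, 0], out[nrec, 1], out[nrec, 2], out[nrec, 3] = x, Tp, V, Vp
            nrec += 1
    return nrec


def _kernel_args(params: DeviceParams, circuit: CircuitParams, n_grid: int = 8193):
    half = params.L / 2.0
    xg = np.linspace(-half, half, n_grid)
    fF = np.asarray(params.potential.force(xg), dtype=float)
    return (xg[0], xg[1] - xg[0], fF, params.R0, params.lambda_,
            params.field_sign * params.q / params.L, params.q_T, params.eta,
            params.C_th, params.kappa, circuit.R_ext, circuit.tau, half)


def integrate(params: DeviceParams, circuit: CircuitParams, V_ext,
              state0, t_max: float, dt: float = 5e-4, record_stride: int = 10,
              method: str = "rk4"):
    """Integrate the deterministic model.

    ``V_ext`` may be a constant or a callable V_ext(t) (slow ramps).
    Returns ``(t, states)`` with states of shape (n, 4).  ``method`` is
    the fixed-step compiled RK4 (default) or ``"lsoda"`` via scipy for
    cross-checks.
    """
    s0 = state0.as_array() if isinstance(state0, DetState) else np.asarray(state0, float)
    n_steps = int(round(t_max / dt))
    if method == "lsoda":
        vfun = V_ext if callable(V_ext) else (lambda t: V_ext)
        sol = solve_ivp(lambda t, y: rhs(y, params, circuit, float(vfun(t))),
                        (0.0, t_max), s0, method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=False,
                        t_eval=np.linspace(0.0, t_max, n_steps // record_stride + 1))
        return sol.t, sol.y.T
    tgrid = np.arange(n_steps) * dt
    vext = np.asarray(V_ext(tgrid), float) if callable(V_ext) \
        else np.full(n_steps, float(V_ext))
    out = np.empty((n_steps // record_stride + 1, 4))
    nrec = _det_rk4(s0, vext, dt, record_stride, *_kernel_args(params, circuit), out)
    t = np.arange(nrec) * (dt * record_stride)
    return t, out[:nrec]


# ---------------------------------------------------------------------------
# limit cycles, continuation, hysteresis, basins
# ---------------------------------------------------------------------------


def detect_limit_cycle(params, circuit, V_ext, state0, t_max: float = 400.0,
                       dt: float = 5e-4, amplitude_floor: float = 1e-3,
                       tail_frac: float = 0.2):
    """Integrate and decide whether the tail oscillates.

    Returns ``(is_cycle, x_min, x_max, tail_states)`` where the min/max of
    x are measured over the final ``tail_frac`` of the run.  An amplitude
    above ``amplitude_floor * L`` counts as a sustained cycle ("spiking"),
    a decaying envelope as convergence to equilibrium.
    """
    t, states = integrate(params, circuit, V_ext, state0, t_max, dt=dt)
    tail = states[int((1.0 - tail_frac) * len(states)):]
    x_min = float(tail[:, 0].min())
    x_max = float(tail[:, 0].max())
    is_cycle = (x_max - x_min) > amplitude_floor * params.L
    return is_cycle, x_min, x_max, tail


def _leading_complex_real(eigs: np.ndarray) -> float:
    """Real part of the leading complex-conjugate pair (NaN if all real)."""
    cplx = eigs[np.abs(np.imag(eigs)) > 1e-12]
    if cplx.size == 0:
        return np.nan
    return float(np.max(np.real(cplx)))


def continue_branches(params: DeviceParams, circuit: CircuitParams,
                      v_min: float, v_max: float, n_v: int = 101,
                      cycle_t_max: float = 400.0,
                      amplitude_floor: float = 1e-3,
                      hopf_tol: float = 1e-6) -> BifurcationDiagram:
    """Sweep V_ext, tracking fixed points, Hopf crossings and limit cycles.

    Hopf candidates are grid intervals on a fixed-point branch where the
    leading complex pair's real part changes sign; each is refined by
    bisection in V_ext until |Re lambda| < ``hopf_tol``.  Limit cycles
    are scanned by long integrations seeded from a perturbed fixed point
    and warm-started from the previous cycle (both sweep directions), and
    recorded as per-V_ext min/max of x.
    """
    v_grid = np.linspace(v_min, v_max, n_v)
    fp_rows = []
    fp_by_v = {}
    for v in v_grid:
        fps = find_fixed_points(v, params, circuit)
        fp_by_v[v] = fps
        for fp in fps:
            fp_rows.append(dict(
                V_ext=v, x=fp.state.x, stability=fp.stability,
                eig_real=float(np.max(np.real(fp.eigenvalues))),
                eig_imag=float(np.max(np.abs(np.imag(fp.eigenvalues)))),
                lead_cplx_re=_leading_complex_real(fp.eigenvalues),
            ))
    fp_df = pd.DataFrame(fp_rows)

    # Hopf candidates: sign change of the leading complex pair's real part
    # between neighbouring grid points on the (nearest-x matched) branch.
    hopf: List[float] = []
    for i in range(n_v - 1):
        va, vb = v_grid[i], v_grid[i + 1]
        for fpa in fp_by_v[va]:
            if not fp_by_v[vb]:
                continue
            fpb = min(fp_by_v[vb], key=lambda f: abs(f.state.x - fpa.state.x))
            ra = _leading_complex_real(fpa.eigenvalues)
            rb = _leading_complex_real(fpb.eigenvalues)
            if np.isnan(ra) or np.isnan(rb) or ra * rb >= 0:
                continue
            v_ref = _refine_hopf(params, circuit, va, vb, fpa.state.x, hopf_tol)
            if v_ref is not None and not any(abs(v_ref - h) < 1e-9 for h in hopf):
                hopf.append(v_ref)

    # limit-cycle scan with warm starts in both directions
    lc = {}
    for direction in (1, -1):
        order = v_grid if direction == 1 else v_grid[::-1]
        warm = None
        for v in order:
            seeds = []
            if warm is not None:
                seeds.append(warm)
            for fp in fp_by_v[v]:
                s = fp.state.as_array()
                s[0] = np.clip(s[0] + 0.05 * params.L, -params.L / 2, params.L / 2)
                seeds.append(s)
            found = None
            for s in seeds:
                ok, x_lo, x_hi, tail = detect_limit_cycle(
                    params, circuit, v, s, t_max=cycle_t_max,
                    amplitude_floor=amplitude_floor)
                if ok:
                    found = (x_lo, x_hi)
                    warm = tail[-1].copy()
                    break
            if found is None:
                warm = None
            else:
                prev = lc.get(v)
                if prev is None or (found[1] - found[0]) > (prev[1] - prev[0]):
                    lc[v] = found
    lc_df = pd.DataFrame(
        [dict(V_ext=v, x_min=lo, x_max=hi) for v, (lo, hi) in sorted(lc.items())]
    )

    windows = _coexistence_windows(v_grid, fp_by_v, lc)
    return BifurcationDiagram(v_grid, fp_df, sorted(hopf), lc_df, windows)


def _refine_hopf(params, circuit, va, vb, x_near, tol, max_iter: int = 60):
    def lead_re(v):
        fps = find_fixed_points(v, params, circuit)
        if not fps:
            return np.nan
        fp = min(fps, key=lambda f: abs(f.state.x - x_near))
        return _leading_complex_real(fp.eigenvalues)

    ra = lead_re(va)
    rb = lead_re(vb)
    if np.isnan(ra) or np.isnan(rb) or ra * rb > 0:
        return None
    for _ in range(max_iter):
        vm = 0.5 * (va + vb)
        rm = lead_re(vm)
        if np.isnan(rm):
            return None
        if abs(rm) < tol:
            return float(vm)
        if ra * rm <= 0:
            vb, rb = vm, rm
        else:
            va, ra = vm, rm
    return float(0.5 * (va + vb))


def _coexistence_windows(v_grid, fp_by_v, lc) -> List[Tuple[float, float]]:
    flags = []
    for v in v_grid:
        has_stable_fp = any(fp.stability == STABLE for fp in fp_by_v[v])
        flags.append(bool(has_stable_fp and v in lc))
    windows = []
    start = None
    for v, f in zip(v_grid, flags):
        if f and start is None:
            start = v
        elif not f and start is not None:
            windows.append((float(start), float(prev)))
            start = None
        prev = v
    if start is not None:
        windows.append((float(start), float(v_grid[-1])))
    return windows


def hysteresis_sweep(params: DeviceParams, circuit: CircuitParams,
                     v_min: float, v_max: float, sweep_time: float = 3000.0,
                     dt: float = 5e-4, n_bins: int = 120,
                     amplitude_floor: float = 1e-3):
    """Slow triangular V_ext ramp up then down through [v_min, v_max].

    Returns ``(up, down, window)``: two DataFrames binned on a common
    V_ext grid with the per-bin mean and amplitude of x, and the V_ext
    interval where the two passes disagree (different oscillation state
    or mean position) beyond tolerance.  The sweep rate must be slow
    compared with every relaxation rate for the paths to be meaningful.
    """
    fps = find_fixed_points(v_min, params, circuit)
    stable = [fp for fp in fps if fp.stability == STABLE]
    start = (stable[0] if stable else fps[0]).state if fps else \
        frozen_x_steady_state(params.well_position, params, circuit, v_min)

    def ramp_up(t):
        return v_min + (v_max - v_min) * np.minimum(t / sweep_time, 1.0)

    t_u, s_u = integrate(params, circuit, ramp_up, start, sweep_time, dt=dt)
    v_u = ramp_up(t_u)

    def ramp_down(t):
        return v_max - (v_max - v_min) * np.minimum(t / sweep_time, 1.0)

    t_d, s_d = integrate(params, circuit, ramp_down, s_u[-1], sweep_time, dt=dt)
    v_d = ramp_down(t_d)

    edges = np.linspace(v_min, v_max, n_bins + 1)

    def binned(v, x):
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            m = idx == b
            if not m.any():
                rows.append(dict(V_ext=0.5 * (edges[b] + edges[b + 1]),
                                 x_mean=np.nan, x_amp=np.nan))
                continue
            rows.append(dict(V_ext=0.5 * (edges[b] + edges[b + 1]),
                             x_mean=float(np.mean(x[m])),
                             x_amp=float(np.max(x[m]) - np.min(x[m]))))
        return pd.DataFrame(rows)

    up = binned(v_u, s_u[:, 0])
    down = binned(v_d, s_d[:, 0])

    floor = amplitude_floor * params.L
    spike_u = up["x_amp"].to_numpy() > 10 * floor
    spike_d = down["x_amp"].to_numpy() > 10 * floor
    mean_diff = np.abs(up["x_mean"].to_numpy() - down["x_mean"].to_numpy())
    # disagreement: one pass oscillates where the other sits on a fixed
    # point, or both are quiescent but at different equilibria; the mean
    # over an oscillating bin is phase-sensitive, so it is only compared
    # where both passes are quiescent
    disagree = (spike_u != spike_d) | (~spike_u & ~spike_d & (mean_diff > 0.02 * params.L))
    centers = up["V_ext"].to_numpy()
    # report the widest contiguous disagreement run (brief mismatches from
    # dynamical delay near a supercritical Hopf onset are not the loop)
    window = None
    best = 0
    i = 0
    while i < disagree.size:
        if disagree[i]:
            j = i
            while j + 1 < disagree.size and disagree[j + 1]:
                j += 1
            if j - i + 1 > best:
                best = j - i + 1
                window = (float(centers[i]), float(centers[j]))
            i = j + 1
        else:
            i += 1
    return up, down, window


def basin_boundary(V_ext: float, params: DeviceParams, circuit: CircuitParams,
                   x0_grid: Sequence[float], t_max: float = 400.0,
                   dt: float = 5e-4, amplitude_floor: float = 1e-3):
    """Classify initial cluster positions as spiking / non-spiking.

    Each x0 starts from the frozen-x steady state of the gradient
    subsystem and is integrated deterministically; sustained tail
    oscillation of x means "spiking", a decaying envelope "non-spiking".
    Returns a DataFrame (x0, spiking) and the boundary estimate x_c
    (midpoint of the first classification flip; NaN if uniform).
    """
    rows = []
    for x0 in x0_grid:
        st = frozen_x_steady_state(float(x0), params, circuit, V_ext)
        ok, _, _, _ = detect_limit_cycle(params, circuit, V_ext, st,
                                         t_max=t_max, dt=dt,
                                         amplitude_floor=amplitude_floor)
        rows.append(dict(x0=float(x0), spiking=bool(ok)))
    df = pd.DataFrame(rows)
    flips = np.nonzero(np.diff(df["spiking"].to_numpy().astype(int)) != 0)[0]
    x_c = float(0.5 * (df["x0"][flips[0]] + df["x0"][flips[0] + 1])) if flips.size else np.nan
    return df, x_c
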