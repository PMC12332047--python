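"""Physical parameters, resistance laws and drive protocols of the device.

The memristor is a gap of size L between the tip of a nearly formed Ag
filament (at ``-L/2``) and the counter-electrode (at ``+L/2``); its
resistance is set by electron tunnelling past one or two mobile Ag
clusters at positions x_i inside the gap:

    one particle:  R(x)      = R0 cosh(x / lambda),  R0 = 2 R_t e^{L / 2 lambda}
    two particles: R(x1, x2) = R_t (e^{(L/2 + x1)/lambda}
                                    + e^{(x2 - x1)/lambda}
                                    + e^{(L/2 - x2)/lambda})

with tunnelling amplitude R_t and effective tunnelling length lambda.
The device sits in series with a load R_ext and a capacitance C
(circuit time constant tau = R_ext C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import yaml

from .potential import ConfigurationError, PotentialSpec, default_potential, locate_well

__all__ = [
    "DeviceParams",
    "CircuitParams",
    "DriveProtocol",
    "ConstantDrive",
    "RampDrive",
    "SinusoidDrive",
    "ConstantTemperature",
    "SinusoidTemperature",
    "resistance_one",
    "resistance_two",
    "resistance_gradient",
    "potential_force",
    "conductance",
    "ConfigurationError",
]


@dataclass(frozen=True)
class DeviceParams:
    """Physical constants of the diffusive memristor.

    All quantities are in a consistent unit system; the shipped reference
    set uses dimensionless units (length in L, resistance in R_ext, time
    in tau = R_ext C, k_B = 1).

    Attributes
    ----------
    R_t : tunnelling resistance amplitude (resistance units)
    lambda_ : effective tunnelling length (length units)
    L : gap size (length units)
    eta : viscosity coefficient of cluster motion (force * time / length)
    q : induced effective cluster charge (force * length / voltage)
    q_T : thermal charge coupling the thermophoretic force to the
        temperature gradient (deterministic model only)
    C_th : thermal capacitance (energy / temperature)
    kappa : Newton-cooling rate constant (1 / time)
    k_B : Boltzmann-like constant fixing the noise scale (energy / temperature)
    n_particles : number of mobile clusters in the gap (1 or 2)
    potential : shape of the electro-chemical potential U(x)
    field_sign : +1 if the electric force q V / L pulls the cluster toward
        the counter-electrode (+x) for V > 0, -1 for the opposite convention
    """

    R_t: float
    lambda_: float
    L: float
    eta: float
    q: float
    q_T: float
    C_th: float
    kappa: float
    k_B: float = 1.0
    n_particles: int = 1
    potential: PotentialSpec = None
    field_sign: int = 1

    def __post_init__(self):
        for name in ("R_t", "lambda_", "L", "eta", "C_th", "k_B"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"DeviceParams.{name} must be > 0")
        if self.kappa < 0:
            raise ConfigurationError("DeviceParams.kappa must be >= 0")
        if self.n_particles not in (1, 2):
            raise ConfigurationError("n_particles must be 1 or 2")
        if self.field_sign not in (1, -1):
            raise ConfigurationError("field_sign must be +1 or -1")
        if self.potential is None:
            object.__setattr__(self, "potential", default_potential(self.L))
        self.potential.check_covers_gap(self.L)

    @property
    def R0(self) -> float:
        """Minimum one-particle resistance, attained at x = 0."""
        return 2.0 * self.R_t * math.exp(self.L / (2.0 * self.lambda_))

    @property
    def well_position(self) -> float:
        wp = self.potential.well_position
        if wp is None:
            wp = locate_well(self.potential, self.L)
        return wp

    def replace(self, **kw) -> "DeviceParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CircuitParams:
    """Series load and capacitance of the neuron circuit.

    tau = R_ext * C is the circuit time constant; D_V is the intensity of
    the external voltage fluctuations (voltage^2 * time) feeding the
    voltage equation.
    """

    R_ext: float = 1.0
    C: float = 1.0
    D_V: float = 0.0

    def __post_init__(self):
        if not (self.R_ext > 0 and self.C > 0):
            raise ConfigurationError("R_ext and C must be > 0")
        if self.D_V < 0:
            raise ConfigurationError("D_V must be >= 0")

    @property
    def tau(self) -> float:
        return self.R_ext * self.C

    def replace(self, **kw) -> "CircuitParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# drive protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantDrive:
    value: float

    def __call__(self, t):
        return np.broadcast_to(self.value, np.shape(t)).astype(float) \
            if np.ndim(t) else float(self.value)


@dataclass(frozen=True)
class RampDrive:
    """Linear ramp start -> end over [0, duration], held constant after."""

    start: float
    end: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("ramp duration must be > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        frac = np.clip(t / self.duration, 0.0, 1.0)
        out = self.start + (self.end - self.start) * frac
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SinusoidDrive:
    """V_DC + V_AC cos(omega t) (or sin with waveform='sin')."""

    dc: float
    ac: float
    omega: float
    waveform: str = "cos"
    phase: float = 0.0

    def __post_init__(self):
        if self.waveform not in ("cos", "sin"):
            raise ConfigurationError("waveform must be 'cos' or 'sin'")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        fn = np.cos if self.waveform == "cos" else np.sin
        out = self.dc + self.ac * fn(self.omega * t + self.phase)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConstantTemperature:
    T0: float

    def __post_init__(self):
        if self.T0 < 0:
            raise ConfigurationError("bath temperature must be >= 0")

    def __call__(self, t):
        return np.broadcast_to(self.T0, np.shape(t)).astype(float) \
            if np.ndim(t) else float(self.T0)


@dataclass(frozen=True)
class SinusoidTemperature:
    """T*(1 + a_T sin(omega t + phi)); requires |a_T| < 1 so T0(t) > 0."""

    T_star: float
    a_T: float
    omega: float
    phi: float = 0.0

    def __post_init__(self):
        if self.T_star <= 0:
            raise ConfigurationError("T_star must be > 0")
        if abs(self.a_T) >= 1:
            raise ConfigurationError("|a_T| must be < 1 to keep T0(t) > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.T_star * (1.0 + self.a_T * np.sin(self.omega * t + self.phi))
        return out if out.ndim else float(out)


VoltageDrive = Union[ConstantDrive, RampDrive, SinusoidDrive]
TemperatureDrive = Union[ConstantTemperature, SinusoidTemperature]


@dataclass(frozen=True)
class DriveProtocol:
    """External voltage V_ext(t) and bath temperature T0(t) time courses."""

    voltage: VoltageDrive
    temperature: TemperatureDrive

    def v_ext(self, t):
        return self.voltage(t)

    def t_bath(self, t):
        return self.temperature(t)

    @staticmethod
    def dc(V_ext: float, T0: float) -> "DriveProtocol":
        return DriveProtocol(ConstantDrive(V_ext), ConstantTemperature(T0))


# ---------------------------------------------------------------------------
# resistance / conductance laws
# ---------------------------------------------------------------------------


def _check_in_gap(x, L, name="x"):
    half = L / 2.0
    x = np.asarray(x, dtype=float)
    if np.any(x < -half):
        raise ValueError(f"{name} < -L/2 = {-half}: position outside the gap")
    if np.any(x > half):
        raise ValueError(f"{name} > +L/2 = {half}: position outside the gap")
    return x


def resistance_one(x, p: DeviceParams):
    """One-particle tunnelling resistance R(x) = R0 cosh(x / lambda)."""
    x = _check_in_gap(x, p.L)
    out = p.R0 * np.cosh(x / p.lambda_)
    return out if np.ndim(out) else float(out)


def resistance_two(x1, x2, p: DeviceParams):
    """Two-particle series tunnelling resistance (requires x1 <= x2)."""
    x1 = _check_in_gap(x1, p.L, "x1")
    x2 = _check_in_gap(x2, p.L, "x2")
    if np.any(np.asarray(x1) > np.asarray(x2)):
        raise ValueError("x1 > x2: particles must be renumbered in ascending order")
    half = p.L / 2.0
    lam = p.lambda_
    out = p.R_t * (
        np.exp((half + x1) / lam) + np.exp((x2 - x1) / lam) + np.exp((half - x2) / lam)
    )
    return out if np.ndim(out) else float(out)


def resistance(positions, p: DeviceParams):
    """Resistance for the configured particle count; positions is scalar/1-elem
    for one particle or a 2-sequence (ascending) for two."""
    if p.n_particles == 1:
        x = positions if np.ndim(positions) == 0 else np.asarray(positions).reshape(-1)[0]
        return resistance_one(x, p)
    x1, x2 = np.asarray(positions).reshape(-1)[:2]
    return resistance_two(x1, x2, p)


def resistance_gradient(x, p: DeviceParams):
    """dR/dx of the one-particle law: (R0 / lambda) sinh(x / lambda)."""
    x = _check_in_gap(x, p.L)
    out = (p.R0 / p.lambda_) * np.sinh(x / p.lambda_)
    return out if np.ndim(out) else float(out)


def potential_force(x, spec: PotentialSpec):
    """Conservative force -dU/dx on a cluster at x."""
    return spec.force(x)


def conductance(x, p: DeviceParams, normalised: bool = True):
    """Memristor conductance G = 1/R; if ``normalised``, G / G_max with
    G_max = 1 / R(0) (one-particle) or 1 / R(0, 0) (two-particle)."""
    if p.n_particles == 1:
        R = resistance_one(x, p)
        Rmin = p.R0
    else:
        x = np.asarray(x)
        R = resistance_two(x[..., 0], x[..., 1], p)
        Rmin = resistance_two(0.0, 0.0, p)
    G = 1.0 / np.asarray(R, dtype=float)
    if normalised:
        G = G * Rmin
    return G if np.ndim(G) else float(G)


# ---------------------------------------------------------------------------
# config file round-trip (flat sections: device, circuit, drive)
# ---------------------------------------------------------------------------

_DEVICE_UNITS = {
    "R_t": "resistance", "lambda_": "length", "L": "length",
    "eta": "force*time/length", "q": "force*length/voltage",
    "q_T": "force/temperature-gradient", "C_th": "energy/temperature",
    "kappa": "1/time", "k_B": "energy/temperature",
}
_CIRCUIT_UNITS = {"R_ext": "resistance", "C": "capacitance", "D_V": "voltage^2*time"}


def _drive_to_dict(protocol: DriveProtocol) -> dict:
    v = protocol.voltage
    if isinstance(v, ConstantDrive):
        vd = {"kind": "constant", "V_DC": v.value}
    elif isinstance(v, RampDrive):
        vd = {"kind": "ramp", "V_start": v.start, "V_end": v.end, "duration": v.duration}
    else:
        vd = {"kind": "sinusoid", "V_DC": v.dc, "V_AC": v.ac, "omega": v.omega,
              "waveform": v.waveform, "phase": v.phase}
    Tdrv = protocol.temperature
    if isinstance(Tdrv, ConstantTemperature):
        td = {"kind": "constant", "T0": Tdrv.T0}
    else:
        td = {"kind": "sinusoid", "T_star": Tdrv.T_star, "a_T": Tdrv.a_T,
              "omega": Tdrv.omega, "phi": Tdrv.phi}
    return {"voltage": vd, "temperature": td,
            "units": {"voltage": "voltage", "temperature": "temperature",
                      "omega": "rad/time", "duration": "time"}}


def _drive_from_dict(d: dict) -> DriveProtocol:
    vd, td = d["voltage"], d["temperature"]
    if vd["kind"] == "constant":
        v = ConstantDrive(vd["V_DC"])
    elif vd["kind"] == "ramp":
        v = RampDrive(vd["V_start"], vd["V_end"], vd["duration"])
    elif vd["kind"] == "sinusoid":
        v = SinusoidDrive(vd["V_DC"], vd["V_AC"], vd["omega"],
                          vd.get("waveform", "cos"), vd.get("phase", 0.0))
    else:
        raise ConfigurationError(f"unknown voltage drive kind {vd['kind']!r}")
    if td["kind"] == "constant":
        T = ConstantTemperature(td["T0"])
    elif td["kind"] == "sinusoid":
        T = SinusoidTemperature(td["T_star"], td["a_T"], td["omega"], td.get("phi", 0.0))
    else:
        raise ConfigurationError(f"unknown temperature drive kind {td['kind']!r}")
    return DriveProtocol(v, T)


def to_config(device: DeviceParams, circuit: CircuitParams,
              protocol: Optional[DriveProtocol] = None) -> dict:
    """Serialise parameter containers to a flat config mapping with unit
    annotations (sections: device, circuit, drive)."""
    pot = device.potential
    if pot.kind == "polynomial":
        pot_d = {"kind": "polynomial",
                 "coefficients": [float(c) for c in pot.coefficients]}
    else:
        pot_d = {"kind": "tabulated",
                 "x_grid": [float(v) for v in pot.x_grid],
                 "u_grid": [float(v) for v in pot.u_grid]}
    if pot.well_position is not None:
        pot_d["well_position"] = float(pot.well_position)
    cfg = {
        "device": {
            **{k: float(getattr(device, k)) for k in _DEVICE_UNITS},
            "n_particles": device.n_particles,
            "field_sign": device.field_sign,
            "potential": pot_d,
            "units": dict(_DEVICE_UNITS),
        },
        "circuit": {
            **{k: float(getattr(circuit, k)) for k in _CIRCUIT_UNITS},
            "units": dict(_CIRCUIT_UNITS),
        },
    }
    if protocol is not None:
        cfg["drive"] = _drive_to_dict(protocol)
    return cfg


def from_config(cfg: dict):
    """Inverse of :func:`to_config`.

    Returns ``(DeviceParams, CircuitParams, DriveProtocol | None)``.
    """
    try:
        d = dict(cfg["device"])
        c = dict(cfg["circuit"])
    except KeyError as e:  # pragma: no cover - defensive
        raise ConfigurationError(f"config missing section {e}") from None
    d.pop("units", None)
    c.pop("units", None)
    pot_d = d.pop("potential", None)
    pot = None
    if pot_d is not None:
        pot = PotentialSpec(
            kind=pot_d["kind"],
            coefficients=pot_d.get("coefficients"),
            x_grid=pot_d.get("x_grid"),
            u_grid=pot_d.get("u_grid"),
            well_position=pot_d.get("well_position"),
        )
    device = DeviceParams(potential=pot, **d)
    circuit = CircuitParams(**c)
    protocol = _drive_from_dict(cfg["drive"]) if "drive" in cfg else None
    return device, circuit, protocol


def save_config(path, device, circuit, protocol=None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config(device, circuit, protocol), fh, sort_keys=False)


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return from_config(cfg)
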