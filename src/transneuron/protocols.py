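"""Reproducible experiment drivers for the four computational studies.

Each driver runs the stochastic simulator over a protocol grid, reduces
the traces with the spike-statistics module, and returns tidy tables; an
optional output directory receives CSVs plus a JSON manifest (parameters,
seeds) sufficient to re-run bit-identically.

Experiments
-----------
* :func:`run_regimes` — DC-drive regime survey with (rate, CV1, burst
  count) labelling: quiescent / regular / sparse / bursting.
* :func:`run_cv_cloud` — (CV1, CV2) clouds over a (V_ext, R_ext, C)
  sweep, optionally scored against an external reference cloud by convex
  hull coverage.
* :func:`run_selectivity` — AC-drive frequency selectivity: 2-D ISI
  histograms versus the stimulus period and rate tuning r(t_p, V_AC)
  with the preferred period t_p*.
* :func:`run_phase_detector` — the two-signal (voltage x bath
  temperature) phase comparator: mean spiking rate versus the relative
  phase phi.
* :func:`estimate_energy_power` — closed-form heating energy per signal
  cycle for a filament of Ag nanoclusters, and the implied power.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CircuitParams,
    DeviceParams,
    DriveProtocol,
    ConstantTemperature,
    SinusoidDrive,
    SinusoidTemperature,
)
from .potential import ConfigurationError
from .reference import (
    PHASE_DETECTOR,
    REFERENCE_DT,
    REFERENCE_T0,
    REGIME_VOLTAGES,
    SPIKE_MIN_PROMINENCE,
    SPIKE_MIN_SEPARATION,
    SPIKE_THRESHOLD_NORM,
    reference_circuit,
    reference_device,
)
from .simulate import SimConfig, Trace, simulate
from .spikes import (
    CVPoint,
    SpikeTrain,
    cv1,
    cv2,
    cv_table,
    detect_spikes,
    hull_coverage,
    isi_histogram_2d,
    psd,
    rate_vs_period,
    segment_bursts,
)

QUIESCENT, REGULAR, SPARSE, BURSTING = "quiescent", "regular", "sparse", "bursting"


@dataclass(frozen=True)
class ExperimentSpec:
    """CLI-facing description of one experiment run."""

    experiment: str
    seeds: Tuple[int, ...] = (1, 2, 3, 4, 5)
    out_dir: Optional[str] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        valid = {"regimes", "cv_cloud", "selectivity", "phase_detector",
                 "bifurcation", "hysteresis"}
        if self.experiment not in valid:
            raise ConfigurationError(f"unknown experiment {self.experiment!r}")
        if len(set(self.seeds)) != len(self.seeds) or not self.seeds:
            raise ConfigurationError("seeds must be a nonempty list of distinct ints")


@dataclass(frozen=True)
class EnergyInputs:
    """Inputs of the per-cycle heating-energy estimate.

    C_Ag: specific heat (J / g degC); rho_Ag: density (g / cm^3);
    N: cluster count; r_Ag_nm: cluster radius (nm); dT: temperature
    swing (degC); f: signal cycle frequency (Hz).
    """

    C_Ag: float = 0.236
    rho_Ag: float = 10.49
    N: int = 10
    r_Ag_nm: float = 10.0
    dT: float = 100.0
    f: float = 1e8

    def __post_init__(self):
        for name in ("C_Ag", "rho_Ag", "N", "r_Ag_nm", "f"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"EnergyInputs.{name} must be > 0")
        if self.dT < 0:
            raise ConfigurationError("EnergyInputs.dT must be >= 0")


def estimate_energy_power(inputs: EnergyInputs) -> Tuple[float, float]:
    """Heating energy per signal cycle E = C rho N (4 pi r^3 / 3) dT, and
    average power P = E f.  Returns (E [J], P [W]).

    Unit chain: r in nm -> cm (1 nm = 1e-7 cm); volume in cm^3 matches
    the density's cm^3; C in J/(g degC) and dT in degC give Joules.
    """
    r_cm = inputs.r_Ag_nm * 1e-7
    volume_cm3 = 4.0 * math.pi * r_cm ** 3 / 3.0
    energy = inputs.C_Ag * inputs.rho_Ag * inputs.N * volume_cm3 * inputs.dT
    return energy, energy * inputs.f


# ---------------------------------------------------------------------------
# shared reduction helpers
# ---------------------------------------------------------------------------


def detect_reference_spikes(trace: Trace, V_ext: float,
                            R_ext: float = 1.0) -> SpikeTrain:
    """Detect spikes on current normalised by V_ext / R_ext.

    An absolute threshold separates relaxation spikes (normalised peaks
    ~10-60) from the latched-conducting plateau (~1) and the quiescent
    divider current (~0.03) at every drive level.
    """
    i_norm = trace.I * R_ext / V_ext
    return detect_spikes(trace.t, i_norm,
                         threshold=SPIKE_THRESHOLD_NORM,
                         min_separation=SPIKE_MIN_SEPARATION,
                         min_prominence=SPIKE_MIN_PROMINENCE)


def classify_regime(train: SpikeTrain,
                    rate_floor: float = 0.02,
                    cv1_regular: float = 0.3,
                    cv1_bursting: float = 1.5,
                    min_bursts: int = 5,
                    burst_isi_factor: float = 5.0) -> str:
    """Label a spike train {quiescent, regular, sparse, bursting}.

    Rules (config-exposed defaults): below ``rate_floor`` -> quiescent;
    CV1 below ``cv1_regular`` -> regular; CV1 of at least
    ``cv1_bursting`` with at least ``min_bursts`` bursts (runs of ISIs
    under ``burst_isi_factor`` x median ISI with 3+ spikes) -> bursting;
    anything else -> sparse.
    """
    if train.rate < rate_floor or len(train) < 5:
        return QUIESCENT
    c1 = cv1(train)
    if c1 < cv1_regular:
        return REGULAR
    bursts, _ = segment_bursts(train, burst_isi_factor * float(np.median(train.isi)))
    n_bursts = sum(1 for b in bursts if b[2] >= 3)
    if c1 >= cv1_bursting and n_bursts >= min_bursts:
        return BURSTING
    return SPARSE


def _write_manifest(out_dir: str, name: str, payload: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, f"{name}_manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# regimes
# ---------------------------------------------------------------------------


def run_regimes(voltages: Optional[Dict[str, float]] = None,
                seeds: Sequence[int] = (1, 2, 3, 4, 5),
                t_max: float = 1500.0,
                device: Optional[DeviceParams] = None,
                circuit: Optional[CircuitParams] = None,
                T0: float = REFERENCE_T0,
                out_dir: Optional[str] = None):
    """DC-drive regime survey at the reference set.

    Simulates each drive level for each seed, detects spikes, computes
    rate / CV1 / CV2 / burst count and a regime label, and reports the
    per-voltage majority label.  Returns ``(table, majority, psds)``
    where psds maps voltage to its averaged power spectrum (last seed).
    Raises if no condition produces spikes (calibration failure).
    """
    voltages = dict(voltages or REGIME_VOLTAGES)
    device = device or reference_device()
    circuit = circuit or reference_circuit()
    rows = []
    psds: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    for name, V in voltages.items():
        for seed in seeds:
            trace = simulate(device, circuit, DriveProtocol.dc(V, T0),
                             SimConfig(dt=REFERENCE_DT, t_max=t_max, seed=seed,
                                       record_stride=20))
            train = detect_reference_spikes(trace, V, circuit.R_ext)
            label = classify_regime(train)
            row = dict(condition=name, V_ext=V, seed=seed, n_spikes=len(train),
                       rate=train.rate, label=label)
            if len(train) >= 5:
                row["cv1"] = cv1(train)
                row["cv2"] = cv2(train)
                bursts, _ = segment_bursts(
                    train, 5.0 * float(np.median(train.isi)))
                row["n_bursts"] = sum(1 for b in bursts if b[2] >= 3)
            rows.append(row)
        psds[V] = psd(trace.t, trace.I * circuit.R_ext / V, segment_length=4096)
    table = pd.DataFrame(rows)
    if (table["n_spikes"] == 0).all():
        raise ConfigurationError(
            "no spikes in any regime condition: calibrated range invalid")
    majority = (table.groupby("condition")["label"]
                .agg(lambda s: s.value_counts().idxmax()).to_dict())
    if out_dir:
        _write_manifest(out_dir, "regimes",
                        dict(voltages=voltages, seeds=list(seeds), t_max=t_max,
                             T0=T0, dt=REFERENCE_DT))
        table.to_csv(os.path.join(out_dir, "regimes.csv"), index=False)
    return table, majority, psds


def spectral_peak_contrast(f: np.ndarray, p: np.ndarray,
                           band: Tuple[float, float] = (0.5, 5.0)) -> float:
    """Peak-to-median power ratio inside the spiking band — a scalar for
    "shows a clear spectral peak" (large) vs "weak frequency dependence"
    (near 1)."""
    m = (f >= band[0]) & (f <= band[1])
    if not m.any():
        return float("nan")
    return float(np.max(p[m]) / np.median(p[m]))


# ---------------------------------------------------------------------------
# CV cloud
# ---------------------------------------------------------------------------


def run_cv_cloud(V_values: Sequence[float] = (1.1, 1.35, 1.6, 1.95, 2.3),
                 R_ext_values: Sequence[float] = (0.8, 1.0, 1.25),
                 C_values: Sequence[float] = (0.5, 1.0, 2.0),
                 seeds: Sequence[int] = (1, 2),
                 t_max: float = 1200.0,
                 device: Optional[DeviceParams] = None,
                 T0: float = REFERENCE_T0,
                 D_V: float = 1e-6,
                 min_isi: int = 10,
                 reference_cloud: Optional[np.ndarray] = None,
                 out_dir: Optional[str] = None):
    """(CV1, CV2) cloud over the (V_ext, R_ext, C) sweep.

    Returns ``(points, table, coverage)``; coverage is the convex-hull
    coverage of ``reference_cloud`` (an (n, 2) array of external CV1/CV2
    pairs, e.g. biological values read from CSV) by the simulated cloud,
    or None if no reference is given.
    """
    device = device or reference_device()
    points: List[CVPoint] = []
    for R_ext in R_ext_values:
        for C in C_values:
            circuit = CircuitParams(R_ext=R_ext, C=C, D_V=D_V)
            for V in V_values:
                for seed in seeds:
                    trace = simulate(device, circuit, DriveProtocol.dc(V, T0),
                                     SimConfig(dt=REFERENCE_DT * circuit.tau,
                                               t_max=t_max * circuit.tau,
                                               seed=seed, record_stride=20))
                    train = detect_reference_spikes(trace, V, R_ext)
                    if len(train.isi) < min_isi:
                        continue
                    points.append(CVPoint(
                        cv1(train), cv2(train), len(train.isi),
                        dict(V_ext=V, R_ext=R_ext, C=C, T0=T0, seed=seed)))
    table = cv_table(points)
    coverage = None
    if reference_cloud is not None:
        if len(table) < 3:
            raise ConfigurationError("cloud too small for hull coverage")
        coverage = hull_coverage(np.asarray(reference_cloud, float),
                                 table[["cv1", "cv2"]].to_numpy())
    if out_dir:
        _write_manifest(out_dir, "cv_cloud",
                        dict(V=list(V_values), R_ext=list(R_ext_values),
                             C=list(C_values), seeds=list(seeds), T0=T0,
                             D_V=D_V, t_max=t_max))
        table.to_csv(os.path.join(out_dir, "cv_cloud.csv"), index=False)
    return points, table, coverage


def load_reference_cloud(path) -> np.ndarray:
    """Read an external (e.g. biological) CV table: CSV with cv1, cv2."""
    df = pd.read_csv(path)
    missing = {"cv1", "cv2"} - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"reference CV table lacks columns: {sorted(missing)}")
    return df[["cv1", "cv2"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------


def run_selectivity(V_DC: float = REGIME_VOLTAGES["regular"],
                    V_AC_fracs: Sequence[float] = (0.25, 0.5, 0.75),
                    t_p_values: Optional[Sequence[float]] = None,
                    seeds: Sequence[int] = (1, 2, 3),
                    t_max: float = 1000.0,
                    device: Optional[DeviceParams] = None,
                    circuit: Optional[CircuitParams] = None,
                    T0: float = REFERENCE_T0,
                    out_dir: Optional[str] = None):
    """AC-drive selectivity: V_ext = V_DC (1 + frac cos(2 pi t / t_p)).

    The stimulus period grid spans the natural ISI measured at the DC
    drive alone.  Returns a dict with the natural period, the 2-D ISI
    histogram (per V_AC), the rate table, the preferred periods t_p*
    per V_AC, and the locking band (periods where the modal ISI is
    within 10% of t_p) for the mid V_AC level.
    """
    device = device or reference_device()
    circuit = circuit or reference_circuit()
    base = simulate(device, circuit, DriveProtocol.dc(V_DC, T0),
                    SimConfig(dt=REFERENCE_DT, t_max=t_max, seed=seeds[0],
                              record_stride=20))
    base_train = detect_reference_spikes(base, V_DC, circuit.R_ext)
    if len(base_train.isi) < 10:
        raise ConfigurationError(
            f"quiescent at V_DC={V_DC}: natural period unavailable")
    natural = float(np.median(base_train.isi))

    if t_p_values is None:
        t_p_values = natural * np.array(
            [0.5, 0.65, 0.8, 0.9, 1.0, 1.1, 1.25, 1.5, 1.8, 2.2])
    trains: Dict[Tuple[float, float], SpikeTrain] = {}
    for frac in V_AC_fracs:
        for t_p in t_p_values:
            omega = 2.0 * math.pi / t_p
            merged: List[np.ndarray] = []
            offset = 0.0
            for seed in seeds:
                protocol = DriveProtocol(
                    SinusoidDrive(V_DC, frac * V_DC, omega, waveform="cos"),
                    ConstantTemperature(T0))
                tr = simulate(device, circuit, protocol,
                              SimConfig(dt=REFERENCE_DT, t_max=t_max,
                                        seed=seed, record_stride=20))
                st = detect_reference_spikes(tr, V_DC, circuit.R_ext)
                merged.append(st.timestamps + offset)
                offset += t_max
            trains[(float(t_p), float(frac))] = SpikeTrain(
                np.concatenate(merged), offset,
                {"t_p": float(t_p), "V_AC": frac * V_DC})

    rate_table, preferred = rate_vs_period(trains)

    mid = V_AC_fracs[len(V_AC_fracs) // 2]
    per_tp = {tp: trains[(tp, mid)] for (tp, v) in trains if v == mid}
    periods, bins, density, mode = isi_histogram_2d(per_tp)
    with np.errstate(invalid="ignore"):
        locked = np.abs(mode - periods) <= 0.1 * periods
    locking_band = periods[locked]

    result = dict(natural_period=natural, t_p_values=np.asarray(t_p_values),
                  rate_table=rate_table, preferred_period=preferred,
                  isi_map=(periods, bins, density, mode),
                  locking_band=locking_band)
    if out_dir:
        _write_manifest(out_dir, "selectivity",
                        dict(V_DC=V_DC, V_AC_fracs=list(V_AC_fracs),
                             t_p=[float(t) for t in t_p_values],
                             seeds=list(seeds), t_max=t_max, T0=T0))
        rate_table.to_csv(os.path.join(out_dir, "selectivity_rates.csv"),
                          index=False)
    return result


# ---------------------------------------------------------------------------
# phase detector
# ---------------------------------------------------------------------------


def run_phase_detector(phi_values: Optional[Sequence[float]] = None,
                       seeds: Sequence[int] = tuple(range(1, 21)),
                       n_periods: float = 5.0,
                       settings: Optional[dict] = None,
                       device: Optional[DeviceParams] = None,
                       circuit: Optional[CircuitParams] = None,
                       out_dir: Optional[str] = None):
    """Two-signal phase comparator.

    Drives V_ext = V_DC + V_AC sin(omega t) against
    T0(t) = T* (1 + a_T sin(omega t + phi)) and measures the mean
    spiking rate per relative phase phi over seeds.  Returns a DataFrame
    (phi, seed, rate), the seed-mean curve, and the phases of its
    minimum and maximum.  The drive straddles the bistable band where
    the relaxation cycle coexists with the latched state, so the bath
    temperature gates the switching between them.
    """
    cfg = dict(PHASE_DETECTOR)
    cfg.update(settings or {})
    if phi_values is None:
        phi_values = np.linspace(0.0, 2.0 * math.pi, 9)[:-1]
    device = (device or reference_device()).replace(C_th=cfg["C_th"])
    circuit = circuit or reference_circuit()
    omega = 2.0 * math.pi / cfg["period"]
    rows = []
    for phi in phi_values:
        for seed in seeds:
            protocol = DriveProtocol(
                SinusoidDrive(cfg["V_DC"], cfg["V_AC"], omega, waveform="sin"),
                SinusoidTemperature(cfg["T_star"], cfg["a_T"], omega, phi))
            tr = simulate(device, circuit, protocol,
                          SimConfig(dt=REFERENCE_DT,
                                    t_max=cfg["period"] * n_periods,
                                    seed=seed, record_stride=20))
            st = detect_reference_spikes(tr, cfg["V_DC"], circuit.R_ext)
            rows.append(dict(phi=float(phi), seed=seed, rate=st.rate))
    table = pd.DataFrame(rows)
    curve = table.groupby("phi")["rate"].agg(["mean", "std"]).reset_index()
    phi_min = float(curve.loc[curve["mean"].idxmin(), "phi"])
    phi_max = float(curve.loc[curve["mean"].idxmax(), "phi"])
    if out_dir:
        _write_manifest(out_dir, "phase_detector",
                        dict(cfg=cfg, phi=[float(p) for p in phi_values],
                             seeds=list(seeds), n_periods=n_periods))
        table.to_csv(os.path.join(out_dir, "phase_rates.csv"), index=False)
    return table, curve, (phi_min, phi_max)
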