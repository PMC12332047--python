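"""Spike-train extraction and statistics.

Implements the two irregularity indices used throughout:

* CV1 — global irregularity, std(ISI) / mean(ISI) (population convention
  by default);
* CV2 — local variability, the trial mean of
  2 |dt_{n+1} - dt_n| / (dt_{n+1} + dt_n) over consecutive inter-spike
  intervals, bounded in [0, 2) by construction.

Plus the supporting machinery: threshold spike detection on current
traces, Welch power spectra, two-dimensional ISI histograms versus the
stimulus period, rate tuning curves with preferred-period extraction,
CV maps over parameter sweeps, burst segmentation and convex-hull
coverage of (CV1, CV2) point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import ConvexHull, Delaunay, QhullError


class InsufficientDataError(ValueError):
    """Raised when a train has too few ISIs for the requested statistic."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike timestamps on an observation window [0, duration]."""

    timestamps: np.ndarray
    duration: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.size and not np.all(np.diff(ts) > 0):
            raise ValueError("spike timestamps must be strictly increasing")
        if ts.size and (ts[0] < 0 or ts[-1] > self.duration):
            raise ValueError("spike timestamps must lie within [0, duration]")
        if not np.all(np.isfinite(ts)):
            raise ValueError("spike timestamps must be finite")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.timestamps)

    @property
    def rate(self) -> float:
        return len(self) / self.duration

    def rescale(self, factor: float) -> "SpikeTrain":
        return SpikeTrain(self.timestamps * factor, self.duration * factor, self.meta)

    def save(self, path) -> None:
        pd.DataFrame({"timestamp": self.timestamps}).to_csv(path, index=False)

    @classmethod
    def load(cls, path, duration: Optional[float] = None) -> "SpikeTrain":
        df = pd.read_csv(path)
        if "timestamp" not in df.columns:
            raise ValueError("spike-train CSV must have a 'timestamp' column")
        ts = df["timestamp"].to_numpy(dtype=float)
        if duration is None:
            duration = float(ts[-1]) if ts.size else 0.0
        return cls(ts, duration, {"source": str(path)})


@dataclass(frozen=True)
class CVPoint:
    """One (CV1, CV2) measurement with its provenance tag."""

    cv1: float
    cv2: float
    n_isi: int
    condition: dict = field(default_factory=dict, compare=False)


def cv_table(points: Iterable[CVPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"cv1": p.cv1, "cv2": p.cv2, "n_isi": p.n_isi}
        row.update(p.condition)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_spikes(t, y, threshold_frac: float = 0.5,
                  min_separation: Optional[float] = None,
                  baseline_quantile: float = 0.5,
                  peak_quantile: float = 0.995,
                  threshold: Optional[float] = None,
                  min_prominence: Optional[float] = None) -> SpikeTrain:
    """Detect spike times as peaks of suprathreshold excursions of y(t).

    By default the threshold is scale-free: baseline (median) plus
    ``threshold_frac`` of the robust amplitude (baseline to the
    ``peak_quantile`` quantile).  Passing ``threshold`` uses that absolute
    level instead (useful on normalised conductance, where a spike means
    the gap actually closes).  Peaks closer than ``min_separation`` are
    merged, keeping the taller.  A flat trace yields an empty train.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("trace contains non-finite samples")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    if min_separation is None:
        min_separation = 2.0 * dt

    duration = float(t[-1])
    if threshold is None:
        baseline = float(np.quantile(y, baseline_quantile))
        peak = float(np.quantile(y, peak_quantile))
        amplitude = peak - baseline
        if amplitude <= 0:
            return SpikeTrain(np.empty(0), duration, {"threshold": None})
        threshold = baseline + threshold_frac * amplitude
        if min_prominence is None:
            min_prominence = 0.5 * threshold_frac * amplitude
    elif min_prominence is None:
        # absolute mode: a spike must rise by at least half the threshold,
        # so micro-ripple on a suprathreshold plateau does not count
        min_prominence = 0.5 * threshold

    distance = max(1, int(round(min_separation / dt)))
    idx, _ = signal.find_peaks(y, height=threshold, distance=distance,
                               prominence=min_prominence)
    # peak height tie-breaking within min_separation is handled by find_peaks
    ts = t[idx]
    return SpikeTrain(ts, duration, {"threshold": threshold, "n": int(ts.size)})


def detect_spikes_trace(trace, channel: str = "I", **kw) -> SpikeTrain:
    """Convenience wrapper: detect spikes on a Trace attribute (default I)."""
    return detect_spikes(trace.t, getattr(trace, channel), **kw)


# ---------------------------------------------------------------------------
# CV statistics
# ---------------------------------------------------------------------------


def _isis(train) -> np.ndarray:
    isi = train.isi if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    if isi.size < 3:
        raise InsufficientDataError(f"need >= 3 ISIs, got {isi.size}")
    return isi


def cv1(train, ddof: int = 0) -> float:
    """std(ISI) / mean(ISI).  Population std by default (ddof=0)."""
    isi = _isis(train)
    return float(np.std(isi, ddof=ddof) / np.mean(isi))


def cv2_pairs(train) -> np.ndarray:
    """Per-pair local variability 2 |dt_{n+1} - dt_n| / (dt_{n+1} + dt_n)."""
    isi = _isis(train)
    a, b = isi[:-1], isi[1:]
    return 2.0 * np.abs(b - a) / (b + a)


def cv2(train) -> float:
    """Trial mean of the pairwise local-variability statistic; in [0, 2)."""
    return float(np.mean(cv2_pairs(train)))


def cv_point(train, condition: Optional[dict] = None) -> CVPoint:
    isi = _isis(train)
    return CVPoint(cv1(train), cv2(train), int(isi.size), condition or {})


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def psd(trace_or_y, y=None, segment_length: Optional[int] = None,
        window: str = "hann"):
    """Averaged-periodogram (Welch) PSD of a uniformly sampled series.

    Accepts either ``psd(trace)`` (uses trace.I) or ``psd(t, y)``.
    The series is mean-removed; 50%-overlapping tapered segments.
    Returns (frequency, power) with density scaling, so the integral of
    the power approximates the series variance (Parseval).
    """
    if y is None:
        t, series = trace_or_y.t, trace_or_y.I
    else:
        t, series = np.asarray(trace_or_y, float), np.asarray(y, float)
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("psd requires uniform sampling")
    fs = 1.0 / dts[0]
    n = series.size
    if segment_length is None:
        segment_length = min(n, max(256, n // 8))
    if segment_length > n:
        raise ValueError("segment_length exceeds trace length")
    f, p = signal.welch(series - np.mean(series), fs=fs, window=window,
                        nperseg=segment_length, noverlap=segment_length // 2,
                        detrend=False)
    return f, p


# ---------------------------------------------------------------------------
# selectivity analyses
# ---------------------------------------------------------------------------


def isi_histogram_2d(trains: Dict[float, SpikeTrain],
                     isi_bins: Optional[np.ndarray] = None,
                     n_bins: int = 60):
    """Column-normalised 2-D histogram of ISI vs stimulus period t_p.

    ``trains`` maps each stimulus period t_p to its spike train.  ISI bins
    are logarithmic by default (bursting spans decades).  Returns
    ``(t_p values, bin edges, density matrix [n_bins, n_tp], mode curve)``
    where the mode curve is the most probable ISI per period (NaN where a
    column is empty).
    """
    periods = np.asarray(sorted(trains), dtype=float)
    if periods.size < 2:
        raise ValueError("need >= 2 stimulus periods")
    all_isi = np.concatenate([trains[p].isi for p in periods if len(trains[p]) > 1])
    if all_isi.size == 0:
        raise ValueError("no ISIs in any train")
    if isi_bins is None:
        lo = max(all_isi.min() * 0.5, 1e-12)
        hi = all_isi.max() * 2.0
        isi_bins = np.geomspace(lo, hi, n_bins + 1)
    density = np.zeros((len(isi_bins) - 1, periods.size))
    mode = np.full(periods.size, np.nan)
    centres = np.sqrt(isi_bins[:-1] * isi_bins[1:])
    for j, p in enumerate(periods):
        isi = trains[p].isi
        if isi.size < 1:
            continue
        h, _ = np.histogram(isi, bins=isi_bins)
        tot = h.sum()
        if tot == 0:
            continue
        density[:, j] = h / tot
        mode[j] = centres[np.argmax(h)]
    return periods, isi_bins, density, mode


def rate_vs_period(trains: Dict[Tuple[float, float], SpikeTrain]):
    """Firing-rate tuning over (t_p, V_AC) and preferred period per V_AC.

    ``trains`` maps (t_p, V_AC) to spike trains.  Returns a tidy frame
    (t_p, V_AC, rate) and a dict V_AC -> t_p*, where t_p* refines the
    discrete argmax by quadratic interpolation through its neighbours.
    """
    rows = [{"t_p": tp, "V_AC": vac, "rate": trains[(tp, vac)].rate}
            for (tp, vac) in trains]
    df = pd.DataFrame(rows).sort_values(["V_AC", "t_p"]).reset_index(drop=True)
    preferred = {}
    for vac, sub in df.groupby("V_AC"):
        tp = sub["t_p"].to_numpy()
        r = sub["rate"].to_numpy()
        if tp.size < 1 or np.all(r == 0):
            preferred[vac] = np.nan
            continue
        k = int(np.argmax(r))
        if 0 < k < tp.size - 1:
            preferred[vac] = _quadratic_vertex(tp[k - 1:k + 2], r[k - 1:k + 2])
        else:
            preferred[vac] = float(tp[k])
    return df, preferred


def _quadratic_vertex(x3, y3) -> float:
    x3 = np.asarray(x3, float)
    y3 = np.asarray(y3, float)
    a, b, _ = np.polyfit(x3, y3, 2)
    if a == 0:
        return float(x3[np.argmax(y3)])
    v = -b / (2 * a)
    return float(np.clip(v, x3[0], x3[-1]))


# ---------------------------------------------------------------------------
# CV maps, bursts, hull coverage
# ---------------------------------------------------------------------------


def cv_map(results: Dict[Tuple[float, float], SpikeTrain],
           min_isi: int = 3):
    """CV1/CV2 matrices over a rectangular (R_ext, V_ext) sweep grid.

    ``results`` maps (R_ext, V_ext) to spike trains.  Cells with fewer
    than ``min_isi`` ISIs are masked (NaN).  Returns
    (R_ext values, V_ext values, CV1 matrix, CV2 matrix, n_isi matrix).
    """
    r_vals = np.asarray(sorted({k[0] for k in results}), float)
    v_vals = np.asarray(sorted({k[1] for k in results}), float)
    shape = (r_vals.size, v_vals.size)
    m1 = np.full(shape, np.nan)
    m2 = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    for (r, v), train in results.items():
        i = int(np.searchsorted(r_vals, r))
        j = int(np.searchsorted(v_vals, v))
        k = len(train.isi)
        n[i, j] = k
        if k >= min_isi:
            m1[i, j] = cv1(train)
            m2[i, j] = cv2(train)
    return r_vals, v_vals, m1, m2, n


def segment_bursts(train: SpikeTrain, isi_threshold: float):
    """Split a train into bursts at ISIs >= isi_threshold.

    Returns ``(bursts, inter_train_intervals)`` where each burst is
    ``(t_start, t_end, n_spikes)`` and the inter-train intervals are the
    gaps (>= threshold) separating consecutive bursts.
    """
    ts = train.timestamps
    if ts.size < 2:
        raise InsufficientDataError("need >= 2 spikes to segment bursts")
    isi = np.diff(ts)
    breaks = np.nonzero(isi >= isi_threshold)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ts.size - 1]))
    bursts = [(float(ts[s]), float(ts[e]), int(e - s + 1))
              for s, e in zip(starts, ends)]
    inter = [float(isi[b]) for b in breaks]
    return bursts, inter


def hull_coverage(reference_points, cloud_points) -> float:
    """Fraction of reference points inside (or on) the convex hull of the
    cloud.  Requires >= 3 non-collinear cloud points."""
    ref = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    cloud = np.asarray(cloud_points, dtype=float).reshape(-1, 2)
    if cloud.shape[0] < 3:
        raise ValueError("cloud needs >= 3 points for a convex hull")
    try:
        hull = ConvexHull(cloud)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear) cloud: {e}") from None
    tri = Delaunay(cloud[hull.vertices])
    inside = tri.find_simplex(ref) >= 0
    # count boundary points as inside despite floating-point grazing
    out = ~inside
    if out.any():
        eqs = hull.equations
        d = ref[out] @ eqs[:, :2].T + eqs[:, 2]
        inside[out] = np.all(d <= 1e-9, axis=1)
    return float(np.mean(inside))
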