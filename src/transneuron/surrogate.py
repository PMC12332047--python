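"""Surrogate spike trains and current traces with known statistics.

Renewal-process generators (periodic, Poisson, gamma, jittered-periodic),
a two-state Markov bursting generator, an alternating-ISI adversarial
train, synthetic current traces with embedded ground-truth spike times,
and (CV1, CV2) point clouds assembled from these classes.  Everything is
a pure function of (spec, seed).

Analytic anchors used in tests: a Poisson train has CV1 = CV2 = 1 (for
i.i.d. exponential X, Y the ratio X/(X+Y) is uniform, so
E[2|X-Y|/(X+Y)] = 2 E|2U-1| = 1); a gamma-renewal train of shape k has
CV1 = 1/sqrt(k); a periodic train has CV1 = CV2 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .spikes import CVPoint, SpikeTrain, cv_point

KINDS = ("periodic", "poisson", "gamma_renewal", "jittered_periodic",
         "two_state_bursting", "alternating_isi")


@dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for one surrogate spike train.

    Parameters by kind:
      periodic           — rate (spikes/time)
      poisson            — rate
      gamma_renewal      — rate, shape
      jittered_periodic  — rate, jitter_sd (per-spike Gaussian jitter)
      two_state_bursting — burst_rate (in-burst Poisson rate),
                           burst_dwell / quiet_dwell (mean exponential
                           dwell times of the two Markov states)
      alternating_isi    — isi_pair = (a, b), deterministic a,b,a,b,...
    """

    kind: str
    duration: float
    rate: float = 1.0
    shape: float = 1.0
    jitter_sd: float = 0.0
    burst_rate: float = 10.0
    burst_dwell: float = 1.0
    quiet_dwell: float = 1.0
    isi_pair: Tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("rate", "shape", "burst_rate", "burst_dwell", "quiet_dwell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if min(self.isi_pair) <= 0:
            raise ValueError("isi_pair values must be > 0")


def generate_train(spec: SurrogateSpec) -> SpikeTrain:
    """Generate one reproducible surrogate train from its spec."""
    rng = np.random.default_rng(spec.seed)
    d = spec.duration
    if spec.kind == "periodic":
        p = 1.0 / spec.rate
        ts = np.arange(p, d, p)
    elif spec.kind == "poisson":
        ts = _renewal(rng.exponential, (1.0 / spec.rate,), d, rng)
    elif spec.kind == "gamma_renewal":
        scale = 1.0 / (spec.rate * spec.shape)
        ts = _renewal(rng.gamma, (spec.shape, scale), d, rng)
    elif spec.kind == "jittered_periodic":
        p = 1.0 / spec.rate
        base = np.arange(p, d, p)
        ts = np.sort(base + rng.normal(0.0, spec.jitter_sd, base.size))
        ts = ts[(ts > 0) & (ts < d)]
        ts = _strictify(ts)
    elif spec.kind == "two_state_bursting":
        ts = _two_state(rng, d, spec.burst_rate, spec.burst_dwell, spec.quiet_dwell)
    else:  # alternating_isi
        a, b = spec.isi_pair
        n = int(d / (a + b)) * 2 + 2
        isi = np.empty(n)
        isi[0::2] = a
        isi[1::2] = b
        ts = np.cumsum(isi)
        ts = ts[ts < d]
    if ts.size < 3:
        warnings.warn(
            f"surrogate spec yields only {ts.size} spikes; best-effort train",
            stacklevel=2,
        )
    return SpikeTrain(ts, d, {"surrogate": spec.kind, "seed": spec.seed})


def _renewal(draw, args, duration, rng) -> np.ndarray:
    expected = duration * 1.2 + 10
    mean_isi = float(np.mean(draw(*args, size=1000)))
    n_guess = int(expected / mean_isi) + 20
    ts: List[np.ndarray] = []
    total = 0.0
    while total < duration:
        isi = draw(*args, size=n_guess)
        chunk = total + np.cumsum(isi)
        ts.append(chunk)
        total = chunk[-1]
    out = np.concatenate(ts)
    return out[out < duration]


def _strictify(ts: np.ndarray) -> np.ndarray:
    """Nudge exactly-coincident sorted timestamps apart (degenerate jitter)."""
    if ts.size < 2:
        return ts
    eps = 1e-12 * max(1.0, ts[-1])
    for i in range(1, ts.size):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + eps
    return ts


def _two_state(rng, duration, burst_rate, burst_dwell, quiet_dwell) -> np.ndarray:
    """Doubly-stochastic Poisson process: exponential dwells alternate
    between a high-rate (burst) state and a silent state."""
    t = 0.0
    bursting = True
    ts: List[float] = []
    while t < duration:
        dwell = rng.exponential(burst_dwell if bursting else quiet_dwell)
        t_end = min(t + dwell, duration)
        if bursting:
            tt = t
            while True:
                tt += rng.exponential(1.0 / burst_rate)
                if tt >= t_end:
                    break
                ts.append(tt)
        t = t_end
        bursting = not bursting
    return np.asarray(ts)


# ---------------------------------------------------------------------------
# synthetic traces for detector validation
# ---------------------------------------------------------------------------


def generate_trace_with_spikes(spike_times, duration: float, dt: float = 1e-3,
                               pulse_width: float = 0.01, amplitude: float = 1.0,
                               baseline: float = 0.0, noise_sd: float = 0.0,
                               seed: int = 0):
    """Synthetic current series with stereotyped Gaussian pulses at known
    times, plus white noise.  Returns ``(t, y, ground_truth_train)``.

    Pulses must be separated by more than 4 pulse widths so the fixture
    is unambiguous.
    """
    ts = np.asarray(spike_times, dtype=float)
    if ts.size and np.any(np.diff(ts) <= 4 * pulse_width):
        raise ValueError("overlapping pulses: separations must exceed 4 pulse widths")
    if ts.size and (ts.min() <= 0 or ts.max() >= duration):
        raise ValueError("spike times must lie strictly inside (0, duration)")
    t = np.arange(0.0, duration, dt)
    y = np.full(t.size, baseline, dtype=float)
    for s in ts:
        y += amplitude * np.exp(-0.5 * ((t - s) / pulse_width) ** 2)
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    truth = SpikeTrain(ts, duration, {"surrogate": "pulse_fixture"})
    return t, y, truth


# ---------------------------------------------------------------------------
# (CV1, CV2) clouds
# ---------------------------------------------------------------------------


def _class_for_centroid(c1: float, c2: float) -> SurrogateSpec:
    """Pick a surrogate family whose realised (CV1, CV2) sits near the
    requested centroid."""
    if c1 < 0.15 and c2 < 0.15:
        return SurrogateSpec("jittered_periodic", duration=1.0, rate=1.0,
                             jitter_sd=max(c1, 1e-3) / (2 ** 0.5))
    if c1 <= 1.05 and abs(c2 - c1) < 0.5:
        shape = 1.0 / max(c1, 0.05) ** 2
        return SurrogateSpec("gamma_renewal", duration=1.0, rate=1.0, shape=shape)
    # high CV1 relative to CV2: bursting
    return SurrogateSpec("two_state_bursting", duration=1.0, burst_rate=20.0,
                         burst_dwell=0.5, quiet_dwell=0.5 * max(c1, 1.0))


def generate_cv_cloud(centroids, n_per_centroid: int = 20,
                      n_isi: int = 500, seed: int = 0) -> List[CVPoint]:
    """Build a (CV1, CV2) cloud by simulating surrogate trains near the
    requested centroids and recomputing their realised statistics.

    ``centroids`` is a sequence of (cv1, cv2) targets with cv1 >= 0 and
    0 <= cv2 < 2.  Realised values are always measured from the generated
    trains, never copied from the request.
    """
    points: List[CVPoint] = []
    rng = np.random.default_rng(seed)
    for (c1, c2) in centroids:
        if c1 < 0 or not (0 <= c2 < 2):
            raise ValueError(f"unreachable centroid ({c1}, {c2}): "
                             "need cv1 >= 0 and 0 <= cv2 < 2")
        proto = _class_for_centroid(c1, c2)
        for _ in range(n_per_centroid):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            duration = n_isi / proto.rate if proto.kind != "two_state_bursting" \
                else n_isi / proto.burst_rate * 2.5
            spec = SurrogateSpec(
                proto.kind, duration=duration, rate=proto.rate,
                shape=proto.shape, jitter_sd=proto.jitter_sd,
                burst_rate=proto.burst_rate, burst_dwell=proto.burst_dwell,
                quiet_dwell=proto.quiet_dwell, seed=sub_seed,
            )
            train = generate_train(spec)
            if len(train) < 4:
                continue
            points.append(cv_point(train, {"kind": spec.kind,
                                           "target_cv1": c1, "target_cv2": c2,
                                           "seed": sub_seed}))
    return points
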