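"""Spike statistics: CV indices, detection, spectra, hulls, bursts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transneuron.spikes import (
    InsufficientDataError,
    SpikeTrain,
    cv1,
    cv2,
    cv2_pairs,
    cv_map,
    detect_spikes,
    hull_coverage,
    isi_histogram_2d,
    psd,
    rate_vs_period,
    segment_bursts,
)
from transneuron.surrogate import SurrogateSpec, generate_train, generate_trace_with_spikes


def train_from_isi(isi):
    ts = np.concatenate(([0.0], np.cumsum(isi)))
    return SpikeTrain(ts, float(ts[-1] + 1))


class TestCV:
    def test_periodic_zero(self):
        tr = train_from_isi(np.full(100, 0.5))
        assert cv1(tr) == 0.0
        assert cv2(tr) == 0.0

    def test_alternating_isi(self):
        # ISIs 1,3,1,3,...: mean 2, deviations +-1 -> CV1 = 0.5; every
        # consecutive pair gives 2*2/4 = 1 -> CV2 = 1
        tr = train_from_isi(np.tile([1.0, 3.0], 200))
        assert cv1(tr) == pytest.approx(0.5, abs=1e-12)
        assert cv2(tr) == pytest.approx(1.0, abs=1e-12)

    def test_exponential_unit_cv(self):
        rng = np.random.default_rng(11)
        tr = train_from_isi(rng.exponential(1.0, 100_000))
        assert cv1(tr) == pytest.approx(1.0, abs=0.01)
        assert cv2(tr) == pytest.approx(1.0, abs=0.01)

    def test_insufficient_data(self):
        tr = train_from_isi([1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            cv1(tr)
        with pytest.raises(InsufficientDataError):
            cv2(tr)

    def test_rescale_invariance(self):
        rng = np.random.default_rng(5)
        tr = train_from_isi(rng.gamma(2.0, 1.0, 500))
        scaled = tr.rescale(37.5)
        assert cv1(scaled) == pytest.approx(cv1(tr), rel=1e-12)
        assert cv2(scaled) == pytest.approx(cv2(tr), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=4,
                    max_size=60))
    def test_cv2_strictly_below_two(self, isi):
        tr = train_from_isi(np.asarray(isi))
        val = cv2(tr)
        assert 0.0 <= val < 2.0
        assert np.all(cv2_pairs(tr) < 2.0)

    def test_cv2_adversarial_alternation(self):
        # extreme alternation a, b with b >> a approaches but never reaches 2
        tr = train_from_isi(np.tile([1e-9, 1e3], 100))
        assert cv2(tr) < 2.0
        assert cv2(tr) > 1.99


class TestDetection:
    def test_five_clean_pulses(self):
        times = [1.0, 3.0, 5.0, 7.0, 9.0]
        t, y, truth = generate_trace_with_spikes(times, duration=10.0)
        st_ = detect_spikes(t, y)
        assert len(st_) == 5
        np.testing.assert_allclose(st_.timestamps, times, atol=2e-3)

    def test_flat_trace_empty(self):
        t = np.linspace(0, 10, 1000)
        st_ = detect_spikes(t, np.ones_like(t))
        assert len(st_) == 0

    def test_close_pulses_merge_to_taller(self):
        t = np.linspace(0, 10, 10001)
        y = np.zeros_like(t)
        y += 1.0 * np.exp(-0.5 * ((t - 5.0) / 0.01) ** 2)
        y += 0.6 * np.exp(-0.5 * ((t - 5.05) / 0.01) ** 2)
        st_ = detect_spikes(t, y, min_separation=0.2)
        # brute-force merge oracle: within min_separation keep the taller
        assert len(st_) == 1
        assert st_.timestamps[0] == pytest.approx(5.0, abs=5e-3)

    def test_nonfinite_rejected(self):
        t = np.linspace(0, 1, 100)
        y = np.zeros_like(t)
        y[50] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spikes(t, y)

    def test_absolute_threshold_ignores_plateau(self):
        t = np.linspace(0, 10, 5000)
        rng = np.random.default_rng(0)
        y = 1.0 + 0.02 * rng.standard_normal(t.size)  # suprathreshold plateau
        st_ = detect_spikes(t, y, threshold=0.5)
        assert len(st_) == 0  # ripple lacks prominence


class TestPSD:
    def test_sinusoid_peak(self):
        t = np.arange(0, 100, 0.01)
        y = np.sin(2 * np.pi * 3.0 * t)
        f, p = psd(t, y, segment_length=4096)
        assert f[np.argmax(p)] == pytest.approx(3.0, abs=0.05)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 200, 0.01)
        y = rng.standard_normal(t.size)
        f, p = psd(t, y, segment_length=2048)
        band1 = p[(f > 1) & (f < 10)].mean()
        band2 = p[(f > 20) & (f < 40)].mean()
        assert band1 == pytest.approx(band2, rel=0.1)

    def test_parseval_within_tolerance(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 100, 0.01)
        y = rng.standard_normal(t.size) + np.sin(2 * np.pi * 2 * t)
        f, p = psd(t, y, segment_length=4096)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(np.var(y), rel=0.05)

    def test_segment_too_long(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(ValueError, match="segment"):
            psd(t, np.zeros_like(t), segment_length=10_000)


class TestISIHistogram:
    def test_periodic_mode_on_identity(self):
        trains = {}
        for p in [0.5, 0.8, 1.2, 2.0]:
            ts = np.arange(p, 200.0, p)
            trains[p] = SpikeTrain(ts, 200.0)
        periods, bins, dens, mode = isi_histogram_2d(trains)
        np.testing.assert_allclose(mode, periods, rtol=0.06)
        np.testing.assert_allclose(dens.sum(axis=0), 1.0)

    def test_poisson_mode_flat(self):
        rng = np.random.default_rng(3)
        trains = {}
        for p in [0.5, 1.0, 2.0]:
            isi = rng.exponential(1.0, 4000)
            ts = np.cumsum(isi)
            trains[p] = SpikeTrain(ts, float(ts[-1] + 1))
        _, _, _, mode = isi_histogram_2d(trains, n_bins=30)
        assert np.nanmax(mode) / np.nanmin(mode) < 2.0  # independent of t_p


class TestRateTuning:
    def test_single_condition(self):
        ts = np.arange(1.0, 50.0)
        trains = {(2.0, 0.5): SpikeTrain(ts, 50.0)}
        df, pref = rate_vs_period(trains)
        assert pref[0.5] == 2.0

    def test_symmetric_peak_interpolated(self):
        # rates 1, 3, 1 at periods 1, 2, 3: vertex of the parabola at 2
        trains = {}
        for tp, r in [(1.0, 1.0), (2.0, 3.0), (3.0, 1.0)]:
            ts = np.arange(1.0 / r, 100.0, 1.0 / r)
            trains[(tp, 0.3)] = SpikeTrain(ts, 100.0)
        _, pref = rate_vs_period(trains)
        assert pref[0.3] == pytest.approx(2.0, abs=0.05)


class TestCVMap:
    def test_masking_and_values(self):
        rng = np.random.default_rng(4)
        results = {}
        for r_ext in [1.0, 2.0]:
            for v in [0.5, 1.0]:
                if v == 0.5:
                    ts = np.array([1.0])  # quiescent: masked
                else:
                    ts = np.cumsum(rng.exponential(1.0, 300))
                results[(r_ext, v)] = SpikeTrain(ts, float(ts[-1] + 1))
        r_vals, v_vals, m1, m2, n = cv_map(results)
        assert np.isnan(m1[:, 0]).all()
        assert np.isfinite(m1[:, 1]).all()
        assert m1[0, 1] == pytest.approx(1.0, abs=0.2)


class TestBursts:
    def test_single_burst_when_threshold_above_period(self):
        tr = train_from_isi(np.full(20, 1.0))
        bursts, inter = segment_bursts(tr, isi_threshold=2.0)
        assert len(bursts) == 1
        assert bursts[0][2] == 21
        assert inter == []

    def test_every_spike_own_burst(self):
        tr = train_from_isi(np.full(9, 1.0))
        bursts, inter = segment_bursts(tr, isi_threshold=0.5)
        assert len(bursts) == 10
        assert all(b[2] == 1 for b in bursts)
        assert len(inter) == 9

    def test_two_state_surrogate_recovers_bursts(self):
        spec = SurrogateSpec("two_state_bursting", duration=400.0,
                             burst_rate=20.0, burst_dwell=2.0,
                             quiet_dwell=8.0, seed=9)
        tr = generate_train(spec)
        bursts, _ = segment_bursts(tr, isi_threshold=1.0)
        big = [b for b in bursts if b[2] >= 3]
        # ~400 / (2 + 8) = 40 burst epochs expected on average
        assert 20 <= len(big) <= 60


class TestHullCoverage:
    @staticmethod
    def brute_force_inside(point, hull_pts):
        """Ray casting against the convex polygon (oracle)."""
        from scipy.spatial import ConvexHull
        hull = ConvexHull(hull_pts)
        poly = hull_pts[hull.vertices]
        x, y = point
        inside = False
        n = len(poly)
        for i in range(n):
            x1, y1 = poly[i]
            x2, y2 = poly[(i + 1) % n]
            # boundary counts as inside
            cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
            d2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
            if d2 > 0 and abs(cross) < 1e-12 * max(1.0, d2) and \
               min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12:
                return True
            if (y1 > y) != (y2 > y):
                if x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                    inside = not inside
        return inside

    def test_unit_square_contains_centre(self):
        cloud = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert hull_coverage([[0.5, 0.5]], cloud) == 1.0

    def test_disjoint_clusters(self):
        cloud = np.array([[0, 0], [1, 0], [0.5, 1]], float)
        ref = np.array([[5, 5], [6, 6]], float)
        assert hull_coverage(ref, cloud) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        cloud = rng.uniform(0, 1, (40, 2))
        ref = rng.uniform(-0.2, 1.2, (200, 2))
        expected = np.mean([self.brute_force_inside(p, cloud) for p in ref])
        assert hull_coverage(ref, cloud) == pytest.approx(expected, abs=1e-12)

    def test_collinear_cloud_rejected(self):
        cloud = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            hull_coverage([[0.5, 0.5]], cloud)


class TestSpikeTrainContainer:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrain(np.array([1.0, 0.5, 2.0]), 3.0)

    def test_round_trip(self, tmp_path):
        tr = train_from_isi(np.random.default_rng(0).exponential(1.0, 50))
        path = tmp_path / "train.csv"
        tr.save(path)
        back = SpikeTrain.load(path, duration=tr.duration)
        np.testing.assert_allclose(back.timestamps, tr.timestamps)

    def test_load_requires_timestamp_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="timestamp"):
            SpikeTrain.load(path)
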