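"""Cross-correlation delay estimation, delay matrices, maps, and features."""

import numpy as np
import pytest

from cortiwave import (GridGeometry, NoiseSpec, WaveSpec, delay_features,
                       delay_map, delay_matrix, peak_time_delay, xcorr_delay)
from cortiwave.core import grid_to_channels
from cortiwave.synth import (gen_plane_wave_event, gen_spiral_wave_event,
                             plane_delay_field, spiral_fields)
from conftest import recording_as_event


def oracle_xcorr_delay(a, b, max_lag):
    """Independent exhaustive lag scan: np.corrcoef on the overlap at every
    lag, same tie rule (smallest |lag|, then negative)."""
    n = len(a)
    best = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            x, y = a[:n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[:n + lag]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if best is None or r > best[1]:
            best = (lag, r)
    return best


class TestXcorrDelay:
    def test_identical_signals_zero_lag_unit_corr(self, rng):
        a = rng.normal(size=300)
        lag, r = xcorr_delay(a, a, max_lag_ms=50.0, fs=1000.0)
        assert lag == 0.0
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_pure_shift_recovered(self, rng):
        a = np.zeros(400)
        a[100:140] = np.hanning(40)
        b = np.roll(a, 10)  # b later by 10 samples
        lag, r = xcorr_delay(a, b, max_lag_ms=50.0, fs=1000.0)
        assert lag == pytest.approx(10.0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_oracle_on_random_pairs(self, rng):
        # brute-force oracle over all lags, 200 random signal pairs
        fs = 1000.0
        for _ in range(200):
            n = int(rng.integers(60, 300))
            max_lag = int(rng.integers(5, n // 2 - 1))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            lag_ms, r = xcorr_delay(a, b, max_lag * 1e3 / fs, fs)
            o_lag, o_r = oracle_xcorr_delay(a, b, max_lag)
            assert lag_ms == o_lag * 1e3 / fs
            assert r == pytest.approx(o_r, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            xcorr_delay(np.zeros(100), np.ones(100) * 2, 10.0, 1000.0)

    def test_max_lag_beyond_half_window_rejected(self, rng):
        a = rng.normal(size=100)
        with pytest.raises(ValueError, match="half the window"):
            xcorr_delay(a, a, max_lag_ms=60.0, fs=1000.0)


class TestDelayMatrix:
    @pytest.fixture(scope="class")
    @classmethod
    def plane_event(cls):
        g = GridGeometry()
        rec, field = gen_plane_wave_event(g, 1000.0, WaveSpec.plane(),
                                          NoiseSpec.silent())
        return recording_as_event(rec), field

    def test_plane_wave_delays_match_truth(self, plane_event):
        ev, field = plane_event
        dm = delay_matrix(ev)
        true_d = field[None, :] - field[:, None]
        err = np.abs(dm.d - true_d)
        frac = np.mean(err <= 1.0 + 1e-9)  # within 1 sample (1 ms)
        assert frac >= 0.95

    def test_antisymmetry_exact(self, plane_event):
        dm = delay_matrix(plane_event[0])
        np.testing.assert_array_equal(dm.d, -dm.d.T)
        np.testing.assert_array_equal(np.diag(dm.d), 0.0)

    def test_identical_channels_zero_matrix(self, grid8, rng):
        seg = np.tile(rng.normal(size=300), (64, 1))
        from cortiwave.events import SpikeEvent

        ev = SpikeEvent(0, (0, 0.3), seg, "ictal", 0, 0.0, 1000.0, grid8)
        dm = delay_matrix(ev)
        np.testing.assert_array_equal(dm.d, 0.0)

    def test_peak_time_method_agrees_with_xcorr(self, plane_event):
        ev, _ = plane_event
        dm_x = delay_matrix(ev)
        dm_p = peak_time_delay(ev)
        agree = np.abs(dm_x.d - dm_p.d) <= 2.0 + 1e-9  # within 2 samples
        assert agree.mean() >= 0.90
        np.testing.assert_array_equal(dm_p.d, -dm_p.d.T)

    def test_bad_channels_stay_nan(self, grid_bad5):
        rec, _ = gen_plane_wave_event(grid_bad5, 1000.0, WaveSpec.plane(),
                                      NoiseSpec.silent())
        dm = delay_matrix(recording_as_event(rec))
        assert np.isnan(dm.d[5, 0]) and np.isnan(dm.d[0, 5])


class TestDelayMap:
    def test_right_to_left_monotone_along_rows(self):
        g = GridGeometry()
        rec, _ = gen_plane_wave_event(g, 1000.0,
                                      WaveSpec.plane(direction=(-1, 0)),
                                      NoiseSpec.silent())
        dm = delay_matrix(recording_as_event(rec))
        gm = delay_map(dm, reference=0)
        diffs = np.diff(gm.values, axis=1)
        assert np.all(diffs <= 1e-9)  # later on the left, earlier on the right

    def test_spiral_map_monotone_in_angle(self):
        g = GridGeometry()
        spec = WaveSpec.spiral()
        rec, _ = gen_spiral_wave_event(g, 1000.0, spec, NoiseSpec.silent())
        dm = delay_matrix(recording_as_event(rec))
        gm = delay_map(dm, reference=0)
        theta, offsets = spiral_fields(g, spec)
        vals = grid_to_channels(gm, g)
        # winding oracle: measured map must track the true angular offsets
        rel = offsets - offsets[0]
        assert np.abs(vals - rel).max() <= 2.0  # 2 samples at 1 kHz

    def test_reference_cell_zero_and_bad_reference_rejected(self, grid_bad5):
        rec, _ = gen_plane_wave_event(grid_bad5, 1000.0, WaveSpec.plane(),
                                      NoiseSpec.silent())
        dm = delay_matrix(recording_as_event(rec))
        gm = delay_map(dm, reference=0)
        assert gm.values[0, 0] == 0.0
        with pytest.raises(ValueError, match="bad"):
            delay_map(dm, reference=5)


class TestDelayFeatures:
    def test_identical_events_identical_rows(self, grid8, rng):
        rec, _ = gen_plane_wave_event(grid8, 1000.0, WaveSpec.plane(),
                                      NoiseSpec.silent())
        evs = [recording_as_event(rec, event_id=i) for i in range(3)]
        feats, good, ref = delay_features(evs)
        assert np.all(feats == feats[0])

    def test_mirrored_directions_negate_features(self, grid8):
        out = []
        for d in ((1, 0), (-1, 0)):
            rec, _ = gen_plane_wave_event(grid8, 1000.0, WaveSpec.plane(direction=d),
                                          NoiseSpec.silent())
            feats, _, _ = delay_features([recording_as_event(rec)])
            out.append(feats[0])
        np.testing.assert_allclose(out[0], -out[1], atol=1e-9)

    def test_noiseless_plane_features_low_rank(self, grid8, rng):
        # rank oracle on constructed delay fields: affine in position, so
        # the reference-relative features span at most 2 directions
        fields = []
        for _ in range(12):
            ang = rng.uniform(0, 2 * np.pi)
            f = plane_delay_field(
                grid8, WaveSpec.plane(direction=(np.cos(ang), np.sin(ang))))
            fields.append(f - f[0])
        s = np.linalg.svd(np.array(fields), compute_uv=False)
        rank = int(np.sum(s > s[0] * 1e-6))
        assert rank <= 3

    def test_estimated_plane_features_concentrate_in_3_components(self, grid8, rng):
        # integer-sample lag quantization adds tiny full-rank noise; the
        # energy must still concentrate in the leading 3 directions
        events = []
        for i in range(12):
            ang = rng.uniform(0, 2 * np.pi)
            rec, _ = gen_plane_wave_event(
                grid8, 1000.0, WaveSpec.plane(direction=(np.cos(ang), np.sin(ang))),
                NoiseSpec.silent())
            events.append(recording_as_event(rec, event_id=i))
        feats, _, _ = delay_features(events)
        s = np.linalg.svd(feats - feats.mean(axis=0), compute_uv=False)
        assert (s[:3] ** 2).sum() / (s ** 2).sum() >= 0.95

    def test_gradient_recovers_speed(self, grid8):
        # fitted delay-map gradient vs channel coordinates -> 1/speed
        speed = 50.0
        rec, field = gen_plane_wave_event(
            grid8, 1000.0, WaveSpec.plane(direction=(-1, 0), speed=speed),
            NoiseSpec(white_sd=200.0, common_mode_amplitude=0.0, seed=5))
        feats, good, ref = delay_features([recording_as_event(rec)])
        pos = grid8.positions()[good]
        A = np.column_stack((np.ones(good.size), pos))
        coef, *_ = np.linalg.lstsq(A, feats[0], rcond=None)
        grad = np.hypot(coef[1], coef[2])  # ms/um
        assert grad == pytest.approx(1.0 / speed, rel=0.10)
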