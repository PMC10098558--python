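"""Preprocessing and windowing: interpolation, gyro bias, median filter,
frame extraction, serialization round-trips."""

import numpy as np
import pytest

from imuhar import signal_io
from imuhar.signal_io import (
    FRAME_HOP,
    FRAME_LEN,
    RawSensorStream,
    UniformRecording,
    estimate_gyro_bias,
    frames_to_seconds,
    interpolate_to_uniform,
    median_filter_channel,
    preprocess_recording,
    window_frames,
)
from imuhar.synthetic_data import SyntheticConfig, generate_label_sequence, synthesize_recording


def _stream(timestamps, samples, sensor="LA"):
    return RawSensorStream(sensor_id=sensor, timestamps=timestamps, samples=samples)


def _jittered_times(n, rng, fs=52.0):
    return np.arange(n) / fs + rng.uniform(-0.3, 0.3, n) / fs


class TestInterpolation:
    def test_constant_channel_stays_constant(self, rng):
        t = _jittered_times(40, rng)
        samples = np.full((40, 6), 3.25)
        out = interpolate_to_uniform(_stream(t, samples))
        assert np.allclose(out, 3.25)

    def test_affine_signal_is_reproduced_exactly(self, rng):
        t = _jittered_times(40, rng)
        samples = np.stack([2.0 * t + c for c in range(6)], axis=1)
        out = interpolate_to_uniform(_stream(t, samples))
        grid = t[0] + np.arange(out.shape[1]) / 52.0
        for c in range(6):
            assert np.allclose(out[c], 2.0 * grid + c, atol=1e-12)

    def test_sine_matches_two_point_interpolation_oracle(self, rng):
        t = np.sort(_jittered_times(80, rng))
        x = np.sin(2 * np.pi * 1.3 * t)
        samples = np.tile(x[:, None], (1, 6))
        out = interpolate_to_uniform(_stream(t, samples))
        grid = t[0] + np.arange(out.shape[1]) / 52.0
        # direct two-point formula per grid point
        expected = np.empty_like(grid)
        for i, g in enumerate(grid):
            j = np.searchsorted(t, g, side="right") - 1
            j = min(max(j, 0), len(t) - 2)
            w = (g - t[j]) / (t[j + 1] - t[j])
            expected[i] = (1 - w) * x[j] + w * x[j + 1]
        assert np.allclose(out[0], expected, atol=1e-10)

    def test_uniform_stream_interpolates_to_identity(self):
        t = np.arange(40) / 52.0
        samples = np.arange(240.0).reshape(40, 6)
        out = interpolate_to_uniform(_stream(t, samples))
        assert out.shape[1] == 40
        assert np.allclose(out, samples.T, atol=1e-9)

    def test_rejects_non_monotone_and_empty(self):
        t = np.arange(8) / 52.0
        t[3] = t[5]
        with pytest.raises(ValueError, match="monotone"):
            _stream(t, np.zeros((8, 6)))
        short = _stream(np.arange(4) / 52.0, np.zeros((4, 6)))
        with pytest.raises(ValueError, match="packets"):
            interpolate_to_uniform(short)


class TestGyroBias:
    def test_constant_channel_returns_value(self):
        assert estimate_gyro_bias(np.full(100, 2.5)) == pytest.approx(2.5)

    def test_zero_variance_run_wins(self, rng):
        x = rng.normal(5.0, 3.0, 300)
        x[100:164] = -1.75  # exactly constant 64-sample run
        assert estimate_gyro_bias(x) == pytest.approx(-1.75)

    def test_matches_exhaustive_scan(self, rng):
        x = rng.normal(size=500)
        best = min(
            range(len(x) - 63), key=lambda i: x[i : i + 64].var()
        )
        assert estimate_gyro_bias(x) == pytest.approx(x[best : best + 64].mean())

    def test_rejects_short_channel(self):
        with pytest.raises(ValueError):
            estimate_gyro_bias(np.zeros(63))

    def test_bias_removal_idempotent(self, rng):
        x = rng.normal(size=300) + 4.0
        x[50:114] = 4.0
        once = x - estimate_gyro_bias(x)
        assert estimate_gyro_bias(once) == pytest.approx(0.0, abs=1e-12)


class TestMedianFilter:
    def test_constant_unchanged(self):
        assert np.allclose(median_filter_channel(np.full(30, 7.0)), 7.0)

    def test_single_spike_removed(self):
        x = np.full(30, 1.0)
        x[15] = 100.0
        assert np.allclose(median_filter_channel(x), 1.0)

    def test_matches_naive_sliding_sort(self, rng):
        x = rng.normal(size=20)
        out = median_filter_channel(x, 5)
        for i in range(20):
            lo, hi = max(0, i - 2), min(20, i + 3)
            r = min(i - lo, hi - 1 - i)
            window = np.sort(x[i - r : i + r + 1])
            assert out[i] == pytest.approx(window[len(window) // 2])

    def test_rejects_even_width(self):
        with pytest.raises(ValueError):
            median_filter_channel(np.zeros(10), 4)

    def test_order_preserving_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        f = np.exp  # strictly increasing
        a = median_filter_channel(f(x), 5)[2:-2]
        b = f(median_filter_channel(x, 5))[2:-2]
        assert np.allclose(a, b)


class TestPreprocess:
    def _clean_streams(self, n=416):
        t = np.arange(n) / 52.0
        streams = {}
        for si, sid in enumerate(signal_io.SENSORS):
            samples = np.zeros((n, 6))
            samples[:, :3] = np.sin(2 * np.pi * 0.7 * t[:, None] + si)
            streams[sid] = _stream(t, samples, sid)
        return streams

    def test_clean_streams_pass_through(self):
        streams = self._clean_streams()
        rec = preprocess_recording(streams)
        # smooth signals: median filtering and interpolation are ~identity
        # (the 5-sample median flattens sine peaks by ~f'' * (2/fs)^2 / 2)
        assert np.allclose(
            rec.signal[0, 5:-5], streams["LA"].samples[5 : rec.n_samples - 5, 0], atol=2e-2
        )

    def test_gyro_offset_removed(self):
        streams = self._clean_streams()
        streams["RA"].samples[:, 3] += 17.0  # constant gyro offset
        rec = preprocess_recording(streams)
        row = rec.signal[6 * 1 + 3]
        assert abs(estimate_gyro_bias(row)) == pytest.approx(0.0, abs=1e-9)

    def test_missing_sensor_rejected(self):
        streams = self._clean_streams()
        del streams["LL"]
        with pytest.raises(ValueError, match="missing sensor"):
            preprocess_recording(streams)

    def test_synthetic_streams_roundtrip_h5(self, tmp_path):
        cfg = SyntheticConfig(n_recordings=1, duration_s=10.0, seed=11)
        rng = np.random.default_rng(0)
        labels = generate_label_sequence(cfg, 520, rng)
        streams, _ = synthesize_recording(cfg, labels, rng)
        path = tmp_path / "rec.h5"
        signal_io.write_recording_h5(path, streams, {"fs": 52.0})
        back, meta = signal_io.read_recording_h5(path)
        assert meta["fs"] == 52.0
        for sid in signal_io.SENSORS:
            assert np.array_equal(back[sid].timestamps, streams[sid].timestamps)
            assert np.array_equal(back[sid].samples, streams[sid].samples)

    def test_stream_csv_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(n_recordings=1, duration_s=5.0, seed=2)
        rng = np.random.default_rng(1)
        labels = generate_label_sequence(cfg, 260, rng)
        streams, _ = synthesize_recording(cfg, labels, rng)
        path = tmp_path / "LA.csv"
        signal_io.write_stream_csv(streams["LA"], path)
        back = signal_io.read_stream_csv(path, "LA")
        assert np.allclose(back.timestamps, streams["LA"].timestamps)
        assert np.allclose(back.samples, streams["LA"].samples)


class TestWindowing:
    @pytest.mark.parametrize(
        "n_samples,expected",
        [(120, 1), (180, 2), (600, 9), (119, 0), (130, 1)],
    )
    def test_frame_counts(self, n_samples, expected):
        rec = UniformRecording(signal=np.zeros((24, n_samples)))
        if expected == 0:
            with pytest.warns(UserWarning):
                ft = window_frames(rec)
        else:
            ft = window_frames(rec)
        assert ft.n_frames == expected

    def test_slices_match_direct_indexing(self, rng):
        sig = rng.normal(size=(24, 600))
        ft = window_frames(UniformRecording(signal=sig))
        for i in range(ft.n_frames):
            assert np.array_equal(ft.frames[i], sig[:, 60 * i : 60 * i + 120])

    def test_every_other_frame_reconstructs_prefix(self, rng):
        sig = rng.normal(size=(24, 600))
        ft = window_frames(UniformRecording(signal=sig))
        recon = np.concatenate([ft.frames[i] for i in range(0, ft.n_frames, 2)], axis=1)
        assert np.array_equal(recon, sig[:, : recon.shape[1]])

    def test_frames_h5_roundtrip(self, tmp_path, rng):
        sig = rng.normal(size=(24, 600))
        ft = window_frames(UniformRecording(signal=sig))
        labels = rng.integers(0, 7, ft.n_frames)
        path = tmp_path / "frames.h5"
        signal_io.write_frames_h5(path, ft, labels)
        back, lab = signal_io.read_frames_h5(path)
        assert np.array_equal(back.frames, ft.frames)
        assert np.array_equal(lab, labels)

    def test_labels_csv_roundtrip(self, tmp_path, rng):
        hard = rng.integers(0, 7, 20)
        path = tmp_path / "labels.csv"
        signal_io.write_labels_csv(hard, path)
        assert np.array_equal(signal_io.read_labels_csv(path), hard)
        soft = rng.random((20, 7))
        soft /= soft.sum(axis=1, keepdims=True)
        signal_io.write_labels_csv(soft, path)
        assert np.allclose(signal_io.read_labels_csv(path), soft)


class TestFrameTiming:
    def test_zero_frames(self):
        assert frames_to_seconds(0) == 0.0

    def test_sixty_frames_span(self):
        assert frames_to_seconds(60) == pytest.approx(69.2, abs=0.05)

    def test_single_hop(self):
        assert frames_to_seconds(1) == pytest.approx(60 / 52)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            frames_to_seconds(-1)
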