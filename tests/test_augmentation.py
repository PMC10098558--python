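"""Augmentation operators: rotations, time warping, dropout variants."""

import numpy as np
import pytest

from imuhar.augmentation import (
    AugmentationConfig,
    apply_sensor_rotation,
    augment_minibatch,
    bottleneck_dropout,
    euler_rotation_matrix,
    input_dropout,
    sample_rotation_angles,
    sensor_dropout_augment,
    time_warp_frame,
)


class TestRotation:
    def test_zero_angles_identity(self):
        assert np.allclose(euler_rotation_matrix(0, 0, 0), np.eye(3))

    def test_orthonormal_det_one(self, rng):
        for _ in range(20):
            a, b, g = rng.uniform(-np.pi, np.pi, 3)
            r = euler_rotation_matrix(a, b, g)
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_yaw_quarter_turn_maps_x_to_y(self):
        r = euler_rotation_matrix(np.pi / 2, 0, 0)
        assert np.allclose(r @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_zero_angles_leave_frame_unchanged(self, single_frame):
        out = apply_sensor_rotation(single_frame, np.zeros((4, 3)))
        assert np.allclose(out, single_frame)

    def test_triad_norms_preserved(self, single_frame, rng):
        angles = sample_rotation_angles(rng)
        out = apply_sensor_rotation(single_frame, angles)
        for start in range(0, 24, 3):
            a = np.linalg.norm(single_frame[start : start + 3], axis=0)
            b = np.linalg.norm(out[start : start + 3], axis=0)
            assert np.allclose(a, b, atol=1e-10)

    def test_inverse_rotation_roundtrip(self, single_frame, rng):
        angles = sample_rotation_angles(rng)
        out = apply_sensor_rotation(single_frame, angles)
        # undo with the transposed matrices triad by triad
        for s in range(4):
            r = euler_rotation_matrix(*angles[s])
            for start in (6 * s, 6 * s + 3):
                out[start : start + 3] = r.T @ out[start : start + 3]
        assert np.allclose(out, single_frame, atol=1e-10)

    def test_angles_within_bound(self, rng):
        angles = sample_rotation_angles(rng, max_deg=10.0)
        assert np.all(np.abs(np.rad2deg(angles)) <= 10.0)

    def test_commutes_with_triad_scaling(self, single_frame, rng):
        angles = sample_rotation_angles(rng)
        a = apply_sensor_rotation(3.0 * single_frame, angles)
        b = 3.0 * apply_sensor_rotation(single_frame, angles)
        assert np.allclose(a, b, atol=1e-10)


class TestTimeWarp:
    def test_identity_at_zero_amplitude(self, single_frame):
        out = time_warp_frame(single_frame, 0.0, 0.7, 0.3)
        assert np.allclose(out, single_frame, atol=1e-12)

    def test_output_length_preserved(self, single_frame, rng):
        for _ in range(5):
            a, w, p = rng.uniform(0, 1, 3)
            out = time_warp_frame(single_frame, a, w, p)
            assert out.shape == single_frame.shape

    def test_constant_channel_unchanged(self, rng):
        frame = np.tile(np.arange(24.0)[:, None], (1, 120))
        out = time_warp_frame(frame, *rng.uniform(0, 1, 3))
        assert np.allclose(out, frame, atol=1e-12)

    def test_endpoints_fixed(self, single_frame, rng):
        out = time_warp_frame(single_frame, 0.9, 0.5, 0.1)
        assert np.allclose(out[:, 0], single_frame[:, 0])
        assert np.allclose(out[:, -1], single_frame[:, -1])

    def test_amplitude_above_one_rejected(self, single_frame):
        with pytest.raises(ValueError):
            time_warp_frame(single_frame, 1.5, 0.5, 0.5)


class TestDropout:
    def test_p_zero_identity(self, frame_batch, rng):
        assert np.array_equal(input_dropout(frame_batch, 0.0, rng), frame_batch)

    def test_p_one_zeroes_everything(self, frame_batch, rng):
        assert np.all(input_dropout(frame_batch, 1.0, rng) == 0.0)

    def test_zeroed_fraction_binomial(self, rng):
        x = np.ones(100_000)
        out = bottleneck_dropout(x, 0.3, rng)
        frac = (out == 0.0).mean()
        se = np.sqrt(0.3 * 0.7 / x.size)
        assert abs(frac - 0.3) < 3 * se

    def test_inverted_scaling_preserves_expectation(self, rng):
        x = np.full(200_000, 5.0)
        out = input_dropout(x, 0.3, rng)
        assert out[out != 0][0] == pytest.approx(5.0 / 0.7)
        assert out.mean() == pytest.approx(5.0, rel=0.02)


class TestSensorDropout:
    def test_p_zero_identity(self, frame_batch, rng):
        assert np.array_equal(sensor_dropout_augment(frame_batch, 0.0, rng), frame_batch)

    def test_triggered_drop_zeroes_one_sensor(self, frame_batch):
        rng = np.random.default_rng(0)
        out = None
        for _ in range(50):
            out = sensor_dropout_augment(frame_batch, 1.0, rng)
            zero_rows = np.all(out == 0.0, axis=(0, 2))
            assert zero_rows.sum() == 6
            s = np.flatnonzero(zero_rows)
            assert np.array_equal(s, np.arange(s[0], s[0] + 6))
            assert s[0] % 6 == 0

    def test_drop_frequencies_match_uniform_choice(self, frame_batch):
        rng = np.random.default_rng(42)
        n = 4000
        counts = np.zeros(4)
        dropped = 0
        for _ in range(n):
            out = sensor_dropout_augment(frame_batch, 0.3, rng)
            zero_rows = np.all(out == 0.0, axis=(0, 2))
            if zero_rows.any():
                dropped += 1
                counts[np.flatnonzero(zero_rows)[0] // 6] += 1
        se_total = np.sqrt(0.3 * 0.7 / n)
        assert abs(dropped / n - 0.3) < 3 * se_total
        se_each = np.sqrt(0.075 * 0.925 / n)
        assert np.all(np.abs(counts / n - 0.075) < 3 * se_each)


class TestComposition:
    def test_none_config_is_identity(self, frame_batch, rng):
        cfg = AugmentationConfig.none()
        assert np.array_equal(augment_minibatch(frame_batch, cfg, rng), frame_batch)

    def test_from_keys_and_active_keys(self):
        cfg = AugmentationConfig.from_keys(["dr1", "drs"])
        assert cfg.active_keys() == ("dr1", "drs")
        with pytest.raises(ValueError):
            AugmentationConfig.from_keys(["bogus"])

    def test_rotation_only_preserves_triad_norms(self, frame_batch):
        rng = np.random.default_rng(1)
        cfg = AugmentationConfig.from_keys(["rot"])
        out = augment_minibatch(frame_batch, cfg, rng)
        a = np.linalg.norm(frame_batch[:, 0:3, :], axis=1)
        b = np.linalg.norm(out[:, 0:3, :], axis=1)
        assert np.allclose(a, b, atol=1e-10)
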