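"""Training-time data augmentation for multi-IMU frames.

Five operators, all identity in evaluation mode:

* input dropout (``dr1``) and bottleneck dropout (``dr2``): element-wise
  inverted dropout at 30% by default;
* sensor dropout (``drs``): with probability p one uniformly chosen sensor's
  six channels are zeroed for the whole minibatch — simulating a lost limb
  sensor;
* sensor rotation (``rot``): per-sensor random Euler rotation (yaw/pitch/
  roll uniform within +-10 degrees) applied to both the accelerometer and
  gyroscope triads, simulating garment-fit variation in sensor pose;
* time warping (``tw``): per-frame sinusoidal modulation of the local
  sampling interval, resampled back to 120 samples so the frame duration is
  preserved — movements speed up and slow down within the frame.

When several operators are enabled they compose in the fixed order
rotation -> time warp -> input dropout -> sensor dropout (bottleneck dropout
lives inside the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import FS_DEFAULT, N_CHANNELS


@dataclass
class AugmentationConfig:
    """Which operators are active and their parameters (Fig-9-style keys:
    dr1 input dropout, dr2 bottleneck dropout, rot rotation, tw time warp,
    drs sensor dropout)."""

    dr1: bool = False
    dr2: bool = False
    rot: bool = False
    tw: bool = False
    drs: bool = False
    input_dropout_p: float = 0.3
    bottleneck_dropout_p: float = 0.3
    sensor_dropout_p: float = 0.3
    rotation_max_deg: float = 10.0

    def __post_init__(self):
        for p in (self.input_dropout_p, self.bottleneck_dropout_p, self.sensor_dropout_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must be in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation bound must be non-negative")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls()

    @classmethod
    def from_keys(cls, keys, **kwargs) -> "AugmentationConfig":
        """Build from a list of operator keys, e.g. ["dr1", "drs"]."""
        valid = {"dr1", "dr2", "rot", "tw", "drs"}
        unknown = set(keys) - valid
        if unknown:
            raise ValueError(f"unknown augmentation keys {sorted(unknown)}")
        return cls(**{k: True for k in keys}, **kwargs)

    def active_keys(self) -> tuple[str, ...]:
        return tuple(k for k in ("dr1", "dr2", "rot", "tw", "drs") if getattr(self, k))


# ----------------------------------------------------------------------
def euler_rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix R = Rz(alpha) Ry(beta) Rx(gamma) (yaw, pitch, roll
    in radians)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cg, -sg], [0.0, sg, cg]])
    return rz @ ry @ rx


def sample_rotation_angles(
    rng: np.random.Generator, max_deg: float = 10.0, n_sensors: int = 4
) -> np.ndarray:
    """(n_sensors, 3) yaw/pitch/roll angles, uniform within +-max_deg, in
    radians."""
    return np.deg2rad(rng.uniform(-max_deg, max_deg, size=(n_sensors, 3)))


def apply_sensor_rotation(frames: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rotate each sensor's acc and gyro triads by that sensor's rotation.

    ``frames``: (..., 24, T); ``angles``: (4, 3) per-sensor yaw/pitch/roll.
    The same matrix multiplies both triads of a sensor at every sample.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[-2] != N_CHANNELS:
        raise ValueError("expected 24-channel frames")
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (4, 3):
        raise ValueError("need one (yaw, pitch, roll) triple per sensor")
    out = frames.copy()
    for s in range(4):
        r = euler_rotation_matrix(*angles[s])
        for triad_start in (6 * s, 6 * s + 3):
            block = out[..., triad_start : triad_start + 3, :]
            out[..., triad_start : triad_start + 3, :] = np.einsum("ij,...jt->...it", r, block)
    return out


def time_warp_frame(
    frame: np.ndarray, a: float, omega: float, phi: float, fs: float = FS_DEFAULT
) -> np.ndarray:
    """Warp one (24, T) frame: the local sampling interval is modulated as
    dt_new = 2 + A sin(2 pi omega t + 2 pi phi), integrated to a new
    timebase, rescaled to the original frame duration and linearly
    resampled back to T uniform samples.

    A in [0, 1] keeps dt_new positive (monotone warp); A = 0 is the
    identity.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("time-warp amplitude A must be in [0, 1]")
    frame = np.asarray(frame, dtype=float)
    t = frame.shape[-1]
    t_old = np.arange(t) / fs
    dt_new = 2.0 + a * np.sin(2.0 * np.pi * omega * t_old + 2.0 * np.pi * phi)
    timebase = np.concatenate([[0.0], np.cumsum(dt_new[:-1])])
    if timebase[-1] == 0.0:
        return frame.copy()
    t_new = timebase / timebase[-1] * t_old[-1]  # rescale: duration preserved
    out = np.empty_like(frame)
    for c in range(frame.shape[0]):
        out[c] = np.interp(t_new, t_old, frame[c])
    return out


def time_warp_batch(frames: np.ndarray, rng: np.random.Generator, fs: float = FS_DEFAULT):
    """Fresh (A, omega, phi) ~ U[0,1] per frame."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        a, omega, phi = rng.uniform(0.0, 1.0, size=3)
        out[i] = time_warp_frame(frame, a, omega, phi, fs)
    return out


def input_dropout(frames: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Element-wise inverted dropout of the input tensor (training only)."""
    return _dropout(frames, p, rng)


def bottleneck_dropout(features: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Element-wise inverted dropout of the bottleneck features."""
    return _dropout(features, p, rng)


def _dropout(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if not 0.0 <= p <= 1.0:
        raise ValueError("dropout probability must be in [0, 1]")
    x = np.asarray(x, dtype=float)
    if p == 0.0:
        return x.copy()
    if p >= 1.0:
        return np.zeros_like(x)
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


def sensor_dropout_augment(
    frames: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """With probability p, zero one uniformly chosen sensor's 6 channels
    across the entire minibatch; otherwise identity."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("sensor dropout probability must be in [0, 1]")
    frames = np.asarray(frames, dtype=float)
    if rng.random() >= p:
        return frames.copy()
    sensor = int(rng.integers(0, 4))
    out = frames.copy()
    out[..., 6 * sensor : 6 * sensor + 6, :] = 0.0
    return out


def augment_minibatch(
    frames: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    fs: float = FS_DEFAULT,
) -> np.ndarray:
    """Apply the enabled input-level operators in the fixed composition
    order rotation -> time warp -> input dropout -> sensor dropout.

    Bottleneck dropout (``dr2``) acts inside the model and is not applied
    here.
    """
    out = np.asarray(frames, dtype=float)
    if cfg.rot:
        out = apply_sensor_rotation(out, sample_rotation_angles(rng, cfg.rotation_max_deg))
    if cfg.tw:
        out = time_warp_batch(out, rng, fs)
    if cfg.dr1:
        out = input_dropout(out, cfg.input_dropout_p, rng)
    if cfg.drs:
        out = sensor_dropout_augment(out, cfg.sensor_dropout_p, rng)
    return out
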