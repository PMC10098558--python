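"""Synthetic multi-IMU infant-movement recordings with known class structure.

The real study data (limb-worn IMUs on freely moving infants) are not
public, so this generator produces recordings with the same plumbing —
52 Hz four-sensor streams packetized in fours with jittered timestamps,
triaxial accelerometer (m/s^2) plus gyroscope (deg/s) channels, constant
per-channel gyroscope bias, and a skewed 7-class movement label
distribution — and a deliberately simple signal model inside:

* per-sample class labels follow a first-order Markov chain whose
  stationary distribution equals the configured priors and whose
  self-transition probability sets the (geometric) dwell time;
* each limb's accelerometer is a slowly drifting gravity vector (norm
  9.81 m/s^2) plus a class- and limb-specific sinusoidal oscillation plus
  Gaussian noise; the gyroscope is a class/limb-specific oscillation plus a
  constant bias plus noise;
* frame labels are derived by majority vote over each 120-sample window
  (ties broken toward the lower class index).

Classes differ in which limbs move and at which frequency/amplitude, which
makes them separable by construction — enough to exercise and validate
every pipeline stage, while making no claim of biomechanical realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import signal_io
from .signal_io import (
    CLASS_NAMES,
    FRAME_HOP,
    FRAME_LEN,
    FS_DEFAULT,
    PACKET_SIZE,
    SENSORS,
    RawSensorStream,
)

GRAVITY = 9.81
ACC_RANGE = 8 * GRAVITY  # +-8 g
GYRO_RANGE = 500.0  # +-500 deg/s

#: per-class motion signature: limb activation weights (LA, RA, LL, RL),
#: oscillation frequency (Hz), accelerometer amplitude (m/s^2), gyroscope
#: amplitude (deg/s).  Classes are separated by limb pattern and frequency.
CLASS_MOTION = {
    "Still": dict(limbs=(0.0, 0.0, 0.0, 0.0), freq=0.0, acc_amp=0.0, gyro_amp=0.0),
    "Proto": dict(limbs=(1.0, 1.0, 1.0, 1.0), freq=0.9, acc_amp=2.0, gyro_amp=40.0),
    "TurnL": dict(limbs=(1.0, 0.1, 1.0, 0.1), freq=1.6, acc_amp=3.0, gyro_amp=70.0),
    "TurnR": dict(limbs=(0.1, 1.0, 0.1, 1.0), freq=1.6, acc_amp=3.0, gyro_amp=70.0),
    "PivotL": dict(limbs=(0.5, 0.1, 1.0, 0.3), freq=2.4, acc_amp=3.0, gyro_amp=80.0),
    "PivotR": dict(limbs=(0.1, 0.5, 0.3, 1.0), freq=2.4, acc_amp=3.0, gyro_amp=80.0),
    "CrawlCommando": dict(limbs=(1.0, 1.0, 1.0, 1.0), freq=3.6, acc_amp=4.5, gyro_amp=110.0),
}

#: frame-count fractions of the real dataset's seven movement categories
SKEWED_PRIORS = (0.5920, 0.2872, 0.0147, 0.0141, 0.0296, 0.0312, 0.0313)

#: nominal gravity direction of each limb sensor in its own frame (unit
#: vectors; arms and legs mounted at different poses)
_MOUNT_DIRECTIONS = np.array(
    [
        [0.80, 0.48, 0.36],  # LA
        [0.80, -0.48, 0.36],  # RA
        [0.20, 0.40, 0.89],  # LL
        [0.20, -0.40, 0.89],  # RL
    ]
)
_MOUNT_DIRECTIONS /= np.linalg.norm(_MOUNT_DIRECTIONS, axis=1, keepdims=True)


def _euler(a: float, b: float, g: float) -> np.ndarray:
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(g), np.sin(g)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    ry = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    rx = np.array([[1.0, 0, 0], [0, cg, -sg], [0, sg, cg]])
    return rz @ ry @ rx


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the study's recording
    conditions (52 Hz, 4 sensors, skewed class distribution, ~20 s dwell
    times), at a configurable shorter duration."""

    n_recordings: int = 8
    duration_s: float = 180.0
    fs: float = FS_DEFAULT
    class_priors: tuple[float, ...] = SKEWED_PRIORS
    self_transition: float = 0.999  # per-sample; mean dwell ~ 19 s at 52 Hz
    noise_acc: float = 0.15  # m/s^2
    noise_gyro: float = 2.0  # deg/s
    gyro_bias_range: float = 2.0  # deg/s, uniform +- per channel
    drift_rate: float = 0.02  # gravity-direction random-walk step (1/sqrt(s))
    orientation_spread_deg: float = 25.0  # posture variation around the mount pose
    jitter_std: float = 0.002  # s; well below half the 19.2 ms sample period
    seed: int = 0

    def __post_init__(self):
        priors = np.asarray(self.class_priors, dtype=float)
        if len(priors) != len(CLASS_NAMES) or np.any(priors < 0) or priors.sum() <= 0:
            raise ValueError("class_priors must be 7 non-negative weights")
        self.class_priors = tuple(priors / priors.sum())
        if not 0.0 <= self.self_transition <= 1.0:
            raise ValueError("self_transition must be in [0, 1]")
        if self.duration_s * self.fs < FRAME_LEN:
            raise ValueError("duration must cover at least one frame")
        if self.jitter_std >= 0.5 / self.fs:
            raise ValueError("timestamp jitter std must stay below half a sample period")

    @classmethod
    def easy_benchmark(cls, seed: int = 0) -> "SyntheticConfig":
        """Benchmark preset with balanced classes and low noise: every class
        is well represented and linearly separable signal structure makes
        near-ceiling classification attainable."""
        return cls(
            n_recordings=8,
            duration_s=180.0,
            class_priors=tuple([1.0 / 7] * 7),
            self_transition=0.999,
            noise_acc=0.1,
            noise_gyro=1.5,
            seed=seed,
        )


@dataclass
class Recording:
    """A preprocessed recording ready for training: windowed frames and
    per-frame integer class labels."""

    recording_id: str
    frames: np.ndarray  # (n_frames, 24, 120)
    labels: np.ndarray  # (n_frames,) int
    subject_id: str = ""


# ----------------------------------------------------------------------
def generate_label_sequence(
    cfg: SyntheticConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample class-id sequence from a first-order Markov chain with
    stationary distribution cfg.class_priors and the configured
    self-transition probability."""
    priors = np.asarray(cfg.class_priors)
    s = cfg.self_transition
    labels = np.empty(n_samples, dtype=int)
    labels[0] = rng.choice(len(priors), p=priors)
    # switch points are geometric; draw the whole switch mask at once
    switch = rng.random(n_samples - 1) >= s
    current = labels[0]
    for i, sw in enumerate(switch, start=1):
        if sw:
            current = rng.choice(len(priors), p=priors)
        labels[i] = current
    return labels


def frame_labels_from_samples(
    sample_labels: np.ndarray, frame_len: int = FRAME_LEN, hop: int = FRAME_HOP
) -> np.ndarray:
    """Majority-vote frame labels over each window; ties break toward the
    lower class index."""
    n = len(sample_labels)
    if n < frame_len:
        return np.empty(0, dtype=int)
    n_frames = (n - frame_len) // hop + 1
    out = np.empty(n_frames, dtype=int)
    for i in range(n_frames):
        window = sample_labels[hop * i : hop * i + frame_len]
        out[i] = int(np.bincount(window, minlength=len(CLASS_NAMES)).argmax())
    return out


def synthesize_recording(
    cfg: SyntheticConfig, sample_labels: np.ndarray, rng: np.random.Generator
) -> tuple[dict[str, RawSensorStream], np.ndarray]:
    """Render raw 4-sensor packet streams for a per-sample label sequence.

    Returns the streams plus the majority-vote frame labels of the raw
    sequence.
    """
    n = (len(sample_labels) // PACKET_SIZE) * PACKET_SIZE
    sample_labels = np.asarray(sample_labels[:n])
    t_nominal = np.arange(n) / cfg.fs

    motion = [CLASS_MOTION[c] for c in CLASS_NAMES]
    limbs = np.array([m["limbs"] for m in motion])  # (7, 4)
    freq = np.array([m["freq"] for m in motion])
    acc_amp = np.array([m["acc_amp"] for m in motion])
    gyro_amp = np.array([m["gyro_amp"] for m in motion])

    f_t = freq[sample_labels]
    osc_phase = 2.0 * np.pi * f_t * t_nominal  # frequency switches at segment bounds

    streams = {}
    for si, sid in enumerate(SENSORS):
        limb_w = limbs[sample_labels, si]
        a_amp = acc_amp[sample_labels] * limb_w
        g_amp = gyro_amp[sample_labels] * limb_w

        # slowly drifting gravity direction: the sensor mount fixes a
        # nominal pose per limb; the realized pose varies with posture
        # within orientation_spread_deg and random-walks slowly from there
        base = _MOUNT_DIRECTIONS[si]
        spread = np.deg2rad(cfg.orientation_spread_deg)
        tilt = rng.uniform(-spread, spread, size=3)
        v = _euler(*tilt) @ base
        steps = rng.normal(0.0, cfg.drift_rate / np.sqrt(cfg.fs), size=(n, 3))
        walk = v + np.cumsum(steps, axis=0)
        g_dir = walk / np.linalg.norm(walk, axis=1, keepdims=True)

        axis_phase = rng.uniform(0, 2 * np.pi, size=3)
        acc = GRAVITY * g_dir + a_amp[:, None] * np.sin(
            osc_phase[:, None] + axis_phase[None, :]
        )
        acc += rng.normal(0.0, cfg.noise_acc, size=(n, 3))

        gyro_phase = rng.uniform(0, 2 * np.pi, size=3)
        bias = rng.uniform(-cfg.gyro_bias_range, cfg.gyro_bias_range, size=3)
        gyro = g_amp[:, None] * np.sin(osc_phase[:, None] + gyro_phase[None, :])
        gyro += bias[None, :] + rng.normal(0.0, cfg.noise_gyro, size=(n, 3))

        samples = np.concatenate(
            [np.clip(acc, -ACC_RANGE, ACC_RANGE), np.clip(gyro, -GYRO_RANGE, GYRO_RANGE)],
            axis=1,
        )
        jitter = np.clip(
            rng.normal(0.0, cfg.jitter_std, size=n), -0.45 / cfg.fs, 0.45 / cfg.fs
        )
        streams[sid] = RawSensorStream(
            sensor_id=sid, timestamps=t_nominal + jitter, samples=samples
        )
    return streams, frame_labels_from_samples(sample_labels)


def make_recording(cfg: SyntheticConfig, index: int) -> Recording:
    """Generate, preprocess and window one recording (deterministic in
    (cfg.seed, index))."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, index)))
    n_samples = int(cfg.duration_s * cfg.fs)
    sample_labels = generate_label_sequence(cfg, n_samples, rng)
    streams, _ = synthesize_recording(cfg, sample_labels, rng)
    rec = signal_io.preprocess_recording(streams, cfg.fs)
    frames = signal_io.window_frames(rec)
    labels = frame_labels_from_samples(sample_labels[: rec.n_samples])
    n = min(frames.n_frames, len(labels))  # interpolation can trim a sample
    return Recording(
        recording_id=f"rec{index:03d}",
        frames=frames.frames[:n],
        labels=labels[:n],
        subject_id=f"subj{index:03d}",
    )


def make_frames_dataset(cfg: SyntheticConfig) -> list[Recording]:
    """The full benchmark as preprocessed, windowed, labeled recordings.
    One synthetic subject per recording."""
    return [make_recording(cfg, i) for i in range(cfg.n_recordings)]


def make_benchmark_dataset(cfg: SyntheticConfig, out_dir, overwrite: bool = False) -> dict:
    """Write the on-disk benchmark layout: per recording a raw HDF5 stream
    container and a frame-label CSV, plus a manifest recording every
    parameter and the seed (byte-identical regeneration)."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(cfg.n_recordings):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, i)))
        n_samples = int(cfg.duration_s * cfg.fs)
        sample_labels = generate_label_sequence(cfg, n_samples, rng)
        streams, frame_labels = synthesize_recording(cfg, sample_labels, rng)
        raw_name = f"rec{i:03d}.h5"
        labels_name = f"rec{i:03d}_labels.csv"
        signal_io.write_recording_h5(
            out / raw_name,
            streams,
            metadata={"fs": cfg.fs, "subject_id": f"subj{i:03d}"},
        )
        signal_io.write_labels_csv(frame_labels, out / labels_name)
        entries.append(
            {"recording_id": f"rec{i:03d}", "raw": raw_name, "labels": labels_name}
        )
    manifest = {"config": asdict(cfg), "recordings": entries}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def load_benchmark_dataset(out_dir) -> list[Recording]:
    """Read a written benchmark back into preprocessed recordings."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    fs = manifest["config"]["fs"]
    recs = []
    for entry in manifest["recordings"]:
        streams, meta = signal_io.read_recording_h5(out / entry["raw"])
        labels = signal_io.read_labels_csv(out / entry["labels"])
        rec = signal_io.preprocess_recording(streams, fs)
        frames = signal_io.window_frames(rec)
        n = min(frames.n_frames, len(labels))
        recs.append(
            Recording(
                recording_id=entry["recording_id"],
                frames=frames.frames[:n],
                labels=np.asarray(labels[:n]),
                subject_id=str(meta.get("subject_id", "")),
            )
        )
    return recs
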