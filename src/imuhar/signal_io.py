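"""Raw multi-IMU stream handling: interpolation, gyro-bias removal, median
filtering, windowing, and on-disk formats.

The recording setup streams each limb sensor (LA, RA, LL, RL: left/right arm,
left/right leg) over Bluetooth in packets of four consecutive time samples
(4 timestamps + 4x6 channel values).  Because the packet timebase is
jittered, every sensor is first linearly interpolated onto an ideal uniform
52 Hz grid shared by all four sensors.  Each gyroscope channel then has its
constant bias estimated from the quietest 64-sample segment of the recording
and subtracted, and every channel is 5-sample median filtered.  The cleaned
(24, N_rec) recording matrix is windowed into 120-sample (2.3 s) frames with
50% overlap, producing the (n_frames, 24, 120) tensor consumed by the
classifiers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

SENSORS = ("LA", "RA", "LL", "RL")
MODALITY_AXES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
#: canonical channel order: sensor-major, accelerometer triad before gyroscope
CHANNEL_NAMES = tuple(f"{s}_{m}" for s in SENSORS for m in MODALITY_AXES)
N_CHANNELS = 24

CLASS_NAMES = (
    "Still",
    "Proto",
    "TurnL",
    "TurnR",
    "PivotL",
    "PivotR",
    "CrawlCommando",
)
N_CLASSES = 7

FS_DEFAULT = 52.0
FRAME_LEN = 120
FRAME_HOP = 60
PACKET_SIZE = 4


# ----------------------------------------------------------------------
@dataclass
class RawSensorStream:
    """Packetized samples from one IMU as streamed over BLE.

    ``timestamps`` are seconds (strictly increasing, jittered around the
    nominal 52 Hz grid); ``samples`` has shape (n, 6) with columns in
    MODALITY_AXES order (acc in m/s^2, gyro in deg/s).  ``n`` is a multiple
    of the 4-sample packet size.
    """

    sensor_id: str
    timestamps: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        if self.sensor_id not in SENSORS:
            raise ValueError(f"unknown sensor id {self.sensor_id!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.timestamps.ndim != 1 or self.samples.shape != (len(self.timestamps), 6):
            raise ValueError("samples must be (n, 6) aligned with timestamps")
        if len(self.timestamps) % PACKET_SIZE != 0:
            raise ValueError("stream length must be a multiple of the 4-sample packet size")
        if len(self.timestamps) >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"non-monotone timestamps in sensor {self.sensor_id}")

    @property
    def n_packets(self) -> int:
        return len(self.timestamps) // PACKET_SIZE


@dataclass
class UniformRecording:
    """24-channel signal matrix on the ideal uniform timebase."""

    signal: np.ndarray  # (24, n_samples)
    fs: float = FS_DEFAULT

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_CHANNELS:
            raise ValueError(f"recording matrix must have {N_CHANNELS} rows")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class FrameTensor:
    """(n_frames, 24, 120) windowed view of a recording."""

    frames: np.ndarray
    frame_len: int = FRAME_LEN
    frame_hop: int = FRAME_HOP
    fs: float = FS_DEFAULT

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != N_CHANNELS:
            raise ValueError("frames must be (n_frames, 24, frame_len)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ----------------------------------------------------------------------
def interpolate_to_uniform(
    stream: RawSensorStream, fs: float = FS_DEFAULT, grid: np.ndarray | None = None
) -> np.ndarray:
    """Linearly interpolate one sensor's channels onto a uniform grid.

    By default the grid starts at the stream's first timestamp and steps
    1/fs without extrapolating past the last timestamp.  An explicit
    ``grid`` (shared across sensors) may be supplied instead; it must lie
    within the stream's time range.

    Returns the (6, n_grid) channel matrix.
    """
    if stream.n_packets < 2:
        raise ValueError("need at least 2 packets to interpolate")
    t = stream.timestamps
    if grid is None:
        grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] < t[0] - 1e-9 or grid[-1] > t[-1] + 1e-9:
            raise ValueError("grid extends beyond the recorded time range")
    out = np.empty((6, len(grid)))
    for c in range(6):
        out[c] = np.interp(grid, t, stream.samples[:, c])
    return out


def estimate_gyro_bias(channel: np.ndarray, window: int = 64) -> float:
    """Bias of a gyroscope channel: mean of the minimum-variance contiguous
    ``window``-sample segment (the quietest stretch of the recording)."""
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 1 or len(channel) < window:
        raise ValueError(f"channel must be 1-D with length >= {window}")
    win = np.lib.stride_tricks.sliding_window_view(channel, window)
    variances = win.var(axis=1)
    return float(win[int(np.argmin(variances))].mean())


def median_filter_channel(channel: np.ndarray, width: int = 5) -> np.ndarray:
    """Sliding median with a symmetrically shrinking window at the edges.

    Interior sample i is the median of samples [i-w//2, i+w//2]; near the
    boundaries the window shrinks (widths 1, 3, ... ) so no samples outside
    the recording are invented.
    """
    if width % 2 == 0:
        raise ValueError("median filter width must be odd")
    channel = np.asarray(channel, dtype=float)
    n = len(channel)
    half = width // 2
    if n <= width:
        out = np.empty(n)
        for i in range(n):
            r = min(i, n - 1 - i, half)
            out[i] = np.median(channel[i - r : i + r + 1])
        return out
    out = np.empty(n)
    core = np.lib.stride_tricks.sliding_window_view(channel, width)
    out[half : n - half] = np.median(core, axis=1)
    for i in range(half):
        r = min(i, half)
        out[i] = np.median(channel[i - r : i + r + 1])
        j = n - 1 - i
        out[j] = np.median(channel[j - r : j + r + 1])
    return out


def preprocess_recording(
    streams: dict[str, RawSensorStream] | list[RawSensorStream],
    fs: float = FS_DEFAULT,
    bias_window: int = 64,
    median_width: int = 5,
) -> UniformRecording:
    """Full preprocessing: shared-grid interpolation, per-gyro-channel bias
    subtraction, per-channel median filtering, canonical channel assembly.

    All four sensors must be present (test-time sensor dropout is a
    downstream simulation, not a preprocessing concern).  The shared grid
    spans the intersection of the four sensors' time ranges, anchored at the
    latest first-timestamp.
    """
    if isinstance(streams, list):
        streams = {s.sensor_id: s for s in streams}
    missing = [s for s in SENSORS if s not in streams]
    if missing:
        raise ValueError(f"missing sensor stream(s): {missing}")
    t0 = max(streams[s].timestamps[0] for s in SENSORS)
    t1 = min(streams[s].timestamps[-1] for s in SENSORS)
    if t1 <= t0:
        raise ValueError("sensor time ranges do not overlap")
    grid = t0 + np.arange(int(np.floor((t1 - t0) * fs)) + 1) / fs
    signal = np.empty((N_CHANNELS, len(grid)))
    for si, sid in enumerate(SENSORS):
        signal[6 * si : 6 * si + 6] = interpolate_to_uniform(streams[sid], fs, grid=grid)
    # gyro bias removal (channels 3..5 of each sensor block)
    if len(grid) >= bias_window:
        for si in range(4):
            for c in range(3, 6):
                row = 6 * si + c
                signal[row] -= estimate_gyro_bias(signal[row], bias_window)
    for row in range(N_CHANNELS):
        signal[row] = median_filter_channel(signal[row], median_width)
    return UniformRecording(signal=signal, fs=fs)


def window_frames(
    rec: UniformRecording, frame_len: int = FRAME_LEN, hop: int = FRAME_HOP
) -> FrameTensor:
    """Window a recording into overlapping frames; frame i covers samples
    [hop*i, hop*i + frame_len).  Trailing samples that do not fill a frame
    are discarded."""
    n = rec.n_samples
    if n < frame_len:
        warnings.warn(f"recording of {n} samples shorter than one frame ({frame_len})")
        return FrameTensor(
            frames=np.empty((0, N_CHANNELS, frame_len)), frame_len=frame_len, frame_hop=hop, fs=rec.fs
        )
    n_frames = (n - frame_len) // hop + 1
    starts = hop * np.arange(n_frames)
    frames = np.stack([rec.signal[:, s : s + frame_len] for s in starts])
    return FrameTensor(frames=frames, frame_len=frame_len, frame_hop=hop, fs=rec.fs)


def frames_to_seconds(n_frames: int, hop: int = FRAME_HOP, fs: float = FS_DEFAULT) -> float:
    """Duration spanned by ``n_frames`` frame hops (n * 60/52 s by default)."""
    if n_frames < 0:
        raise ValueError("frame count must be non-negative")
    return n_frames * hop / fs


# ----------------------------------------------------------------------
# on-disk formats
def write_stream_csv(stream: RawSensorStream, path) -> None:
    """One CSV per sensor: packet_id, timestamp_s, acc_x..gyro_z."""
    df = pd.DataFrame(stream.samples, columns=list(MODALITY_AXES))
    df.insert(0, "timestamp_s", stream.timestamps)
    df.insert(0, "packet_id", np.arange(len(stream.timestamps)) // PACKET_SIZE)
    df.to_csv(path, index=False)


def read_stream_csv(path, sensor_id: str) -> RawSensorStream:
    df = pd.read_csv(path)
    return RawSensorStream(
        sensor_id=sensor_id,
        timestamps=df["timestamp_s"].to_numpy(),
        samples=df[list(MODALITY_AXES)].to_numpy(),
    )


def write_recording_h5(path, streams: dict[str, RawSensorStream], metadata: dict | None = None):
    """Single-container format bundling the four raw sensor streams."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "imuhar-raw-v1"
        for key, value in (metadata or {}).items():
            f.attrs[key] = value
        for sid, stream in streams.items():
            g = f.create_group(sid)
            g.create_dataset("timestamps", data=stream.timestamps)
            g.create_dataset("samples", data=stream.samples)


def read_recording_h5(path) -> tuple[dict[str, RawSensorStream], dict]:
    streams = {}
    with h5py.File(path, "r") as f:
        metadata = {k: v for k, v in f.attrs.items() if k != "format"}
        for sid in SENSORS:
            if sid in f:
                streams[sid] = RawSensorStream(
                    sensor_id=sid,
                    timestamps=f[sid]["timestamps"][...],
                    samples=f[sid]["samples"][...],
                )
    return streams, metadata


def write_labels_csv(labels: np.ndarray, path, class_names=CLASS_NAMES) -> None:
    """Frame labels: hard (frame_index, class) or soft (7 probability columns)."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        df = pd.DataFrame(
            {"frame_index": np.arange(len(labels)), "class": [class_names[i] for i in labels]}
        )
    else:
        if not np.allclose(labels.sum(axis=1), 1.0):
            raise ValueError("soft label rows must sum to 1")
        df = pd.DataFrame(labels, columns=[f"p_{c}" for c in class_names])
        df.insert(0, "frame_index", np.arange(len(labels)))
    df.to_csv(path, index=False)


def read_labels_csv(path, class_names=CLASS_NAMES) -> np.ndarray:
    df = pd.read_csv(path)
    if "class" in df.columns:
        lut = {c: i for i, c in enumerate(class_names)}
        return df["class"].map(lut).to_numpy(dtype=int)
    return df[[f"p_{c}" for c in class_names]].to_numpy(dtype=float)


def write_frames_h5(path, frames: FrameTensor, labels: np.ndarray | None = None) -> None:
    """Preprocessed container: the frame tensor plus channel-order metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "imuhar-frames-v1"
        f.attrs["fs"] = frames.fs
        f.attrs["frame_hop"] = frames.frame_hop
        f.attrs["channel_names"] = json.dumps(list(CHANNEL_NAMES))
        f.create_dataset("frames", data=frames.frames)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels))


def read_frames_h5(path) -> tuple[FrameTensor, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        frames = FrameTensor(
            frames=f["frames"][...],
            frame_hop=int(f.attrs["frame_hop"]),
            fs=float(f.attrs["fs"]),
        )
        labels = f["labels"][...] if "labels" in f else None
    return frames, labels
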