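"""Sensor-encoder architectures: five ways to map a (24, 120) frame to a
compact per-frame bottleneck feature vector (160-dimensional by default).

The five kinds differ in how they fuse channels within and across the four
limb sensors:

``dense``
    Flatten all 24 x 120 = 2880 scalars and apply four fully connected
    layers (first with tanh) down to the bottleneck.  No weight sharing;
    the high-parameter anchor point.
``conv1d``
    The 24 channels are fully connected into the filter channels of a stack
    of 1-D convolutions (kernel 5, stride 2, each halving the time axis),
    then flattened and projected to the bottleneck.
``conv2d_i``
    Separate accelerometer and gyroscope paths.  In each path a first 2-D
    convolution fuses every sensor's xyz triad into sensor-level channels
    and a second fuses the four sensor rows; 1-D convolutions and two fully
    connected mixing layers follow the path concatenation.
``conv2d_is``
    As ``conv2d_i`` plus a third, shared path whose first-layer filters are
    applied to both the accelerometer and the gyroscope images with tied
    weights.
``conv2d_si``
    One shared per-sensor submodule (acc, gyro and shared paths over a
    single sensor's 6 x 120 block) applied to each of the four sensors with
    identical weights and no intersensor mixing anywhere; the four
    per-sensor feature blocks are concatenated.  The bottleneck is therefore
    4 x per_sensor_dim wide, and permuting input sensor blocks permutes the
    output blocks identically.

Hidden widths are configuration choices of this package (the architecture
family fixes only the fusion topology); defaults are in ``EncoderSpec``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, Conv2d, Linear, Module, Tensor, concat
from .signal_io import FRAME_LEN, N_CHANNELS

ENCODER_KINDS = ("dense", "conv1d", "conv2d_i", "conv2d_is", "conv2d_si")

#: channel-row indices of the accelerometer / gyroscope triads, sensor-major
ACC_ROWS = np.array([6 * s + a for s in range(4) for a in range(3)])
GYRO_ROWS = ACC_ROWS + 3


@dataclass
class EncoderSpec:
    """Architecture hyperparameters for :func:`build_encoder`."""

    kind: str = "conv2d_si"
    bottleneck_dim: int = 160
    per_sensor_dim: int | None = None  # conv2d_si; bottleneck = 4 * this
    dense_hidden: tuple[int, ...] = (256, 256, 256)
    conv1d_channels: tuple[int, ...] = (64, 64, 96, 96)
    conv2d_channels: int = 32
    fc_width: int = 256
    negative_slope: float = 0.01
    frame_len: int = FRAME_LEN
    n_sensors: int = 4

    def __post_init__(self):
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {self.kind!r}; choose from {ENCODER_KINDS}")
        if self.kind == "conv2d_si":
            if self.per_sensor_dim is None:
                if self.bottleneck_dim % self.n_sensors != 0:
                    raise ValueError(
                        "conv2d_si bottleneck_dim must be divisible by the sensor count"
                    )
                self.per_sensor_dim = self.bottleneck_dim // self.n_sensors
            else:
                self.bottleneck_dim = self.per_sensor_dim * self.n_sensors


def _out_len(t: int, n_halvings: int) -> int:
    for _ in range(n_halvings):
        t = -(-t // 2)
    return t


class DenseEncoder(Module):
    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        dims = [N_CHANNELS * spec.frame_len, *spec.dense_hidden]
        self.hidden = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], spec.bottleneck_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        h = x.reshape(n, -1)
        for layer in self.hidden:
            h = layer(h).tanh()
        return self.out(h)


class Conv1dEncoder(Module):
    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        chans = [N_CHANNELS, *spec.conv1d_channels]
        self.convs = [
            Conv1d(a, b, 5, rng, stride=2, padding="half")
            for a, b in zip(chans[:-1], chans[1:])
        ]
        t_final = _out_len(spec.frame_len, len(self.convs))
        self.out = Linear(chans[-1] * t_final, spec.bottleneck_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(self.spec.negative_slope)
        return self.out(h.reshape(x.data.shape[0], -1))


class _ModalityPath(Module):
    """xyz fusion -> sensor fusion -> two 1-D convolutions, for one
    modality image of shape (N, c_in, 4*3, 120)."""

    def __init__(self, c_in: int, c: int, slope: float, rng: np.random.Generator):
        super().__init__()
        self.slope = slope
        self.fuse_xyz = Conv2d(c_in, c, (3, 5), (3, 2), rng)
        self.fuse_sensors = Conv2d(c, c, (4, 5), (1, 2), rng)
        self.conv_a = Conv1d(c, c, 5, rng, stride=2, padding="half")
        self.conv_b = Conv1d(c, c, 5, rng, stride=2, padding="half")

    def forward(self, x: Tensor) -> Tensor:
        h = self.fuse_xyz(x).leaky_relu(self.slope)
        h = self.fuse_sensors(h).leaky_relu(self.slope)
        n, c = h.data.shape[0], h.data.shape[1]
        h = h.reshape(n, c, h.data.shape[-1])
        h = self.conv_a(h).leaky_relu(self.slope)
        h = self.conv_b(h).leaky_relu(self.slope)
        return h.reshape(n, -1)


class Conv2dPathEncoder(Module):
    """conv2d_i (two modality paths) or conv2d_is (plus a shared path whose
    xyz-fusion filters are tied across modalities)."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator, shared: bool):
        super().__init__()
        self.spec = spec
        self.shared = shared
        c = spec.conv2d_channels
        slope = spec.negative_slope
        self.acc_path = _ModalityPath(1, c, slope, rng)
        self.gyro_path = _ModalityPath(1, c, slope, rng)
        if shared:
            self.shared_fuse_xyz = Conv2d(1, c, (3, 5), (3, 2), rng)
            self.shared_fuse_sensors = Conv2d(2 * c, c, (4, 5), (1, 2), rng)
            self.shared_conv_a = Conv1d(c, c, 5, rng, stride=2, padding="half")
            self.shared_conv_b = Conv1d(c, c, 5, rng, stride=2, padding="half")
        t_final = _out_len(spec.frame_len, 4)
        n_paths = 3 if shared else 2
        self.fc_mix = Linear(n_paths * c * t_final, spec.fc_width, rng)
        self.out = Linear(spec.fc_width, spec.bottleneck_dim, rng)

    def _shared_path(self, x_acc: Tensor, x_gyro: Tensor) -> Tensor:
        # tied xyz-fusion filters, applied to each modality image separately
        slope = self.spec.negative_slope
        a = self.shared_fuse_xyz(x_acc).leaky_relu(slope)
        g = self.shared_fuse_xyz(x_gyro).leaky_relu(slope)
        h = concat([a, g], axis=1)  # (N, 2c, 4, 60)
        h = self.shared_fuse_sensors(h).leaky_relu(slope)
        n, c = h.data.shape[0], h.data.shape[1]
        h = h.reshape(n, c, h.data.shape[-1])
        h = self.shared_conv_a(h).leaky_relu(slope)
        h = self.shared_conv_b(h).leaky_relu(slope)
        return h.reshape(n, -1)

    def forward(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        x_acc = x[:, ACC_ROWS, :].reshape(n, 1, 12, self.spec.frame_len)
        x_gyro = x[:, GYRO_ROWS, :].reshape(n, 1, 12, self.spec.frame_len)
        paths = [self.acc_path(x_acc), self.gyro_path(x_gyro)]
        if self.shared:
            paths.append(self._shared_path(x_acc, x_gyro))
        h = concat(paths, axis=1)
        h = self.fc_mix(h).leaky_relu(self.spec.negative_slope)
        return self.out(h)


class Conv2dSensorEncoder(Module):
    """conv2d_si: a single per-sensor submodule (acc, gyro, shared paths)
    applied to every sensor with identical weights; no intersensor mixing."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c = spec.conv2d_channels
        self.acc_conv = Conv2d(1, c, (3, 5), (3, 2), rng)
        self.gyro_conv = Conv2d(1, c, (3, 5), (3, 2), rng)
        self.shared_conv = Conv2d(1, c, (3, 5), (3, 2), rng)
        self.conv_a = Conv1d(4 * c, c, 5, rng, stride=2, padding="half")
        self.conv_b = Conv1d(c, c, 5, rng, stride=2, padding="half")
        t_final = _out_len(spec.frame_len, 3)
        self.out = Linear(c * t_final, spec.per_sensor_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        ns = self.spec.n_sensors
        slope = self.spec.negative_slope
        # fold sensors into the batch axis: shared weights, no cross-talk
        h = x.reshape(n * ns, 1, 6, self.spec.frame_len)
        h_acc = h[:, :, 0:3, :]
        h_gyro = h[:, :, 3:6, :]
        paths = [
            self.acc_conv(h_acc).leaky_relu(slope),
            self.gyro_conv(h_gyro).leaky_relu(slope),
            self.shared_conv(h_acc).leaky_relu(slope),
            self.shared_conv(h_gyro).leaky_relu(slope),
        ]
        z = concat(paths, axis=1)  # (N*ns, 4c, 1, 60)
        z = z.reshape(n * ns, z.data.shape[1], z.data.shape[-1])
        z = self.conv_a(z).leaky_relu(slope)
        z = self.conv_b(z).leaky_relu(slope)
        z = self.out(z.reshape(n * ns, -1))  # (N*ns, per_sensor_dim)
        return z.reshape(n, ns * self.spec.per_sensor_dim)


def build_encoder(spec: EncoderSpec, seed: int | np.random.Generator = 0) -> Module:
    """Construct a randomly initialized encoder of the requested kind."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.kind == "dense":
        return DenseEncoder(spec, rng)
    if spec.kind == "conv1d":
        return Conv1dEncoder(spec, rng)
    if spec.kind == "conv2d_i":
        return Conv2dPathEncoder(spec, rng, shared=False)
    if spec.kind == "conv2d_is":
        return Conv2dPathEncoder(spec, rng, shared=True)
    if spec.kind == "conv2d_si":
        return Conv2dSensorEncoder(spec, rng)
    raise ValueError(f"unknown encoder kind {spec.kind!r}")


def encode(model: Module, frames: np.ndarray, batch: int = 256) -> np.ndarray:
    """Deterministic inference: (n_frames, 24, 120) -> (n_frames, D)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != N_CHANNELS:
        raise ValueError("frames must be (n_frames, 24, frame_len)")
    model.eval()
    chunks = [
        model(Tensor(frames[i : i + batch])).data for i in range(0, len(frames), batch)
    ]
    return np.concatenate(chunks, axis=0) if chunks else np.empty((0, 0))


def count_parameters(model: Module) -> int:
    """Total trainable scalars, biases included."""
    return model.n_parameters()


def estimate_flops(model_or_spec: Module | EncoderSpec, seed: int = 0) -> float:
    """MFLOPs of encoding a single frame (2 FLOPs per multiply-accumulate
    plus one per bias add).  For the sensor-independent encoder the cost of
    one sensor's submodule is reported, matching its embedded-deployment
    reading."""
    model = (
        build_encoder(model_or_spec, seed)
        if isinstance(model_or_spec, EncoderSpec)
        else model_or_spec
    )
    spec = model.spec
    model.eval()
    model(Tensor(np.zeros((1, N_CHANNELS, spec.frame_len))))
    total = 0.0
    for m in model.modules():
        total += 2.0 * getattr(m, "last_macs", 0.0) + getattr(m, "last_adds", 0.0)
    if spec.kind == "conv2d_si":
        total /= spec.n_sensors
    return total / 1e6


def summarize(model: Module) -> list[tuple[str, str, int]]:
    """(name, layer type, parameter count) rows for an architecture audit."""
    rows = []

    def walk(mod: Module, prefix: str):
        own = sum(p.data.size for p in mod._params)
        if own:
            rows.append((prefix or "<root>", type(mod).__name__, int(own)))
        for name, value in mod.__dict__.items():
            if isinstance(value, Module):
                walk(value, f"{prefix}.{name}" if prefix else name)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        walk(item, f"{prefix}.{name}[{i}]" if prefix else f"{name}[{i}]")

    walk(model, "")
    return rows
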