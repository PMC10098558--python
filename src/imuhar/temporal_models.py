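"""Time-series modeling heads: from a bottleneck feature sequence to
per-frame 7-class movement probabilities.

Five interchangeable kinds:

``dense``
    One hidden fully connected layer applied frame-wise — no temporal
    modeling at all; the low anchor for the comparison.
``lstm`` / ``gru``
    A unidirectional recurrent layer followed by the softmax head; causal
    (the output at frame t depends only on frames <= t).
``bgru``
    Forward and backward GRUs whose output sequences are concatenated
    before the final fully connected layer; non-causal.
``wavenet``
    Stacked blocks of gated dilated 1-D convolutions with residual and skip
    connections (tanh(filter) * sigmoid(gate) per block, 1x1 residual/skip
    projections, skip-sum head).  Four blocks with dilations [1, 2, 4, 8]
    and kernel 5 by default; dilation spaces the taps, so the stack's
    receptive field is 1 + (kernel - 1) * sum(dilations) frames.  The
    convolutions are centered by default (classification is offline), with
    a causal mode available.

Training processes sequences in minibatches of consecutive frames with zero
initial recurrent state and no state carry-over between minibatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import GRU, LSTM, Conv1d, Linear, Module, Tensor, concat, softmax
from .signal_io import N_CLASSES

TEMPORAL_KINDS = ("dense", "lstm", "gru", "bgru", "wavenet")


@dataclass
class TemporalSpec:
    """Architecture hyperparameters for :func:`build_temporal`."""

    kind: str = "wavenet"
    input_dim: int = 160
    hidden_dim: int = 160
    n_classes: int = N_CLASSES
    wavenet_blocks: tuple[int, ...] = (1, 2, 4, 8)  # dilation per block
    wavenet_kernel: int = 5
    wavenet_channels: int = 64  # residual and skip width
    causal: bool = False
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.kind not in TEMPORAL_KINDS:
            raise ValueError(f"unknown temporal kind {self.kind!r}; choose from {TEMPORAL_KINDS}")
        d = np.asarray(self.wavenet_blocks)
        if len(d) == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("wavenet dilations must be positive and increasing")
        if not self.causal and self.wavenet_kernel % 2 == 0:
            raise ValueError("centered wavenet requires an odd kernel")


class DenseTemporal(Module):
    def __init__(self, spec: TemporalSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.hidden = Linear(spec.input_dim, spec.hidden_dim, rng)
        self.head = Linear(spec.hidden_dim, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.hidden(x).leaky_relu(self.spec.negative_slope))


class RecurrentTemporal(Module):
    def __init__(self, spec: TemporalSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        cell = LSTM if spec.kind == "lstm" else GRU
        self.rnn = cell(spec.input_dim, spec.hidden_dim, rng)
        self.head = Linear(spec.hidden_dim, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.rnn(x))


class BidirectionalGRUTemporal(Module):
    def __init__(self, spec: TemporalSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.fwd = GRU(spec.input_dim, spec.hidden_dim, rng)
        self.bwd = GRU(spec.input_dim, spec.hidden_dim, rng)
        self.head = Linear(2 * spec.hidden_dim, spec.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h_fwd = self.fwd(x)
        h_bwd = self.bwd(x.flip(0)).flip(0)
        return self.head(concat([h_fwd, h_bwd], axis=1))


class _WaveNetBlock(Module):
    def __init__(self, spec: TemporalSpec, dilation: int, rng: np.random.Generator):
        super().__init__()
        c = spec.wavenet_channels
        pad = "causal" if spec.causal else "same"
        # filter and gate computed by one conv with 2c output channels
        self.gated = Conv1d(c, 2 * c, spec.wavenet_kernel, rng, dilation=dilation, padding=pad)
        self.res_proj = Conv1d(c, c, 1, rng, padding=(0, 0))
        self.skip_proj = Conv1d(c, c, 1, rng, padding=(0, 0))
        self.c = c

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        fg = self.gated(x)
        z = fg[:, : self.c, :].tanh() * fg[:, self.c :, :].sigmoid()
        return self.res_proj(z) + x, self.skip_proj(z)


class WaveNetTemporal(Module):
    def __init__(self, spec: TemporalSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c = spec.wavenet_channels
        self.input_proj = Conv1d(spec.input_dim, c, 1, rng, padding=(0, 0))
        self.blocks = [_WaveNetBlock(spec, d, rng) for d in spec.wavenet_blocks]
        self.head_a = Conv1d(c, c, 1, rng, padding=(0, 0))
        self.head_b = Conv1d(c, spec.n_classes, 1, rng, padding=(0, 0))

    def forward(self, x: Tensor) -> Tensor:
        # (T, D) -> (1, D, T)
        t_len = x.data.shape[0]
        h = x.transpose(1, 0).reshape(1, self.spec.input_dim, t_len)
        h = self.input_proj(h)
        skips = None
        for block in self.blocks:
            h, s = block(h)
            skips = s if skips is None else skips + s
        slope = self.spec.negative_slope
        out = self.head_a(skips.leaky_relu(slope)).leaky_relu(slope)
        out = self.head_b(out)  # (1, n_classes, T)
        return out.reshape(self.spec.n_classes, t_len).transpose(1, 0)


def build_temporal(spec: TemporalSpec, seed: int | np.random.Generator = 0) -> Module:
    """Construct a randomly initialized temporal model of the requested kind."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.kind == "dense":
        return DenseTemporal(spec, rng)
    if spec.kind in ("lstm", "gru"):
        return RecurrentTemporal(spec, rng)
    if spec.kind == "bgru":
        return BidirectionalGRUTemporal(spec, rng)
    if spec.kind == "wavenet":
        return WaveNetTemporal(spec, rng)
    raise ValueError(f"unknown temporal kind {spec.kind!r}")


def receptive_field_frames(spec: TemporalSpec) -> int:
    """Receptive field (frames) of the dilated-convolution stack:
    1 + (kernel - 1) * sum(dilations)."""
    if spec.kind != "wavenet":
        raise ValueError("receptive field is defined for the wavenet kind only")
    return 1 + (spec.wavenet_kernel - 1) * int(np.sum(spec.wavenet_blocks))


def predict_sequence(
    encoder: Module,
    temporal: Module,
    frames: np.ndarray,
    block_len: int = 100,
) -> np.ndarray:
    """Full-pipeline inference: (n_frames, 24, 120) -> (n_frames, n_classes)
    softmax rows.  Frames are processed in blocks of ``block_len``
    consecutive frames with zero initial state, mirroring training."""
    frames = np.asarray(frames, dtype=float)
    encoder.eval()
    temporal.eval()
    out = []
    for i in range(0, len(frames), block_len):
        chunk = frames[i : i + block_len]
        feats = encoder(Tensor(chunk))
        logits = temporal(feats)
        out.append(softmax(logits.data, axis=-1))
    if not out:
        n_cls = getattr(temporal.spec, "n_classes", N_CLASSES)
        return np.empty((0, n_cls))
    return np.concatenate(out, axis=0)
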