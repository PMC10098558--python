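"""Neural-network building blocks on top of the autograd core.

Layers record the multiply-accumulate count of their most recent forward
pass (``last_macs`` / ``last_adds``, normalized per input sample), which is
what the architecture-level FLOP accounting sums up.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, matmul, pad1d, pad2d, unfold1d, unfold2d

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Conv2d",
    "Dropout",
    "GRU",
    "LSTM",
    "half_pad",
]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True
        self._params: list[Tensor] = []

    # -- traversal -----------------------------------------------------
    def submodules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for sub in self.submodules():
            yield from sub.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            params.extend(m._params)
        return params

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.weight = Tensor(_uniform_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (n_out,), n_in), requires_grad=True)
        self._params = [self.weight, self.bias]
        self.last_macs = 0.0
        self.last_adds = 0.0

    def forward(self, x: Tensor) -> Tensor:
        rows = x.data.size // x.data.shape[-1]
        self.last_macs = float(self.n_in * self.n_out * rows)
        self.last_adds = float(self.n_out * rows)
        return matmul(x, self.weight) + self.bias


def half_pad(t: int, kernel: int, stride: int, dilation: int = 1) -> tuple[int, int]:
    """Zero-padding (left, right) so an input of length ``t`` maps to
    ``ceil(t / stride)`` output positions."""
    span = (kernel - 1) * dilation + 1
    target = -(-t // stride)
    total = max(0, stride * (target - 1) + span - t)
    return total // 2, total - total // 2


class Conv1d(Module):
    """1-D convolution over (N, C, T), optionally dilated.

    ``padding`` is either an explicit (left, right) pair, ``"half"`` (output
    length ceil(T/stride)), ``"same"`` (centered, stride must be 1) or
    ``"causal"`` (left-only).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        dilation: int = 1,
        padding="half",
    ):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        self.padding = padding
        fan_in = c_in * kernel
        self.weight = Tensor(_uniform_init(rng, (c_out, fan_in), fan_in), requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (c_out, 1), fan_in), requires_grad=True)
        self._params = [self.weight, self.bias]
        self.last_macs = 0.0
        self.last_adds = 0.0

    def _pads(self, t: int) -> tuple[int, int]:
        if isinstance(self.padding, tuple):
            return self.padding
        span = (self.kernel - 1) * self.dilation
        if self.padding == "half":
            return half_pad(t, self.kernel, self.stride, self.dilation)
        if self.padding == "same":
            return span // 2, span - span // 2
        if self.padding == "causal":
            return span, 0
        raise ValueError(f"unknown padding {self.padding!r}")

    def forward(self, x: Tensor) -> Tensor:
        n, _, t = x.data.shape
        left, right = self._pads(t)
        u = unfold1d(pad1d(x, left, right), self.kernel, self.stride, self.dilation)
        ck, l_out = u.data.shape[1], u.data.shape[2]
        # fold batch and time into one GEMM: (c_out, ck) @ (ck, N*L)
        u2 = u.transpose(1, 0, 2).reshape(ck, n * l_out)
        out = matmul(self.weight, u2).reshape(self.c_out, n, l_out).transpose(1, 0, 2)
        out = out + self.bias
        self.last_macs = float(self.c_in * self.kernel * self.c_out * l_out * n)
        self.last_adds = float(self.c_out * l_out * n)
        return out


class Conv2d(Module):
    """2-D convolution over (N, C, H, W) with explicit spatial padding on W
    ("half" behavior) and exact fit on H (the channel-fusion axis)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        rng: np.random.Generator,
        pad_w: str = "half",
    ):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad_w = pad_w
        fan_in = c_in * kernel[0] * kernel[1]
        self.weight = Tensor(_uniform_init(rng, (c_out, fan_in), fan_in), requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, (c_out, 1), fan_in), requires_grad=True)
        self._params = [self.weight, self.bias]
        self.last_macs = 0.0
        self.last_adds = 0.0

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        if (h - kh) % sh != 0:
            raise ValueError(f"height {h} does not fit kernel {kh} stride {sh} exactly")
        if self.pad_w == "half":
            left, right = half_pad(w, kw, sw)
        else:
            left = right = 0
        xp = pad2d(x, (0, 0), (left, right))
        hout = (h - kh) // sh + 1
        wout = (xp.data.shape[-1] - kw) // sw + 1
        u = unfold2d(xp, self.kernel, self.stride)
        ck, l_out = u.data.shape[1], u.data.shape[2]
        u2 = u.transpose(1, 0, 2).reshape(ck, n * l_out)
        out = matmul(self.weight, u2).reshape(self.c_out, n, l_out).transpose(1, 0, 2)
        out = out + self.bias
        self.last_macs = float(self.c_in * kh * kw * self.c_out * hout * wout * n)
        self.last_adds = float(self.c_out * hout * wout * n)
        return out.reshape(n, self.c_out, hout, wout)


class Dropout(Module):
    """Inverted dropout: surviving activations are scaled by 1/(1-p) during
    training so inference is the identity."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dropout probability must be in [0, 1], got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.p >= 1.0:
            return x * np.zeros_like(x.data)
        rng = self.rng if self.rng is not None else np.random.default_rng()
        mask = (rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class GRU(Module):
    """Unidirectional gated recurrent unit over a (T, D) sequence.

    Zero initial state; returns the (T, H) output sequence.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        h = n_hidden
        self.wx = Tensor(_uniform_init(rng, (n_in, 3 * h), n_in), requires_grad=True)
        self.wh = Tensor(_uniform_init(rng, (h, 3 * h), h), requires_grad=True)
        self.b = Tensor(_uniform_init(rng, (3 * h,), n_in), requires_grad=True)
        self._params = [self.wx, self.wh, self.b]
        self.last_macs = 0.0
        self.last_adds = 0.0

    def forward(self, x: Tensor) -> Tensor:
        t_len = x.data.shape[0]
        h = self.n_hidden
        ht = Tensor(np.zeros((1, h)))
        gx_all = matmul(x, self.wx) + self.b  # (T, 3H)
        outs = []
        for t in range(t_len):
            gx = gx_all[t : t + 1]
            gh = matmul(ht, self.wh)
            z = (gx[:, :h] + gh[:, :h]).sigmoid()
            r = (gx[:, h : 2 * h] + gh[:, h : 2 * h]).sigmoid()
            n = (gx[:, 2 * h :] + r * gh[:, 2 * h :]).tanh()
            ht = (1.0 - z) * ht + z * n
            outs.append(ht)
        self.last_macs = float(3 * (self.n_in * h + h * h) * t_len)
        self.last_adds = float(3 * h * t_len)
        return concat(outs, axis=0)


class LSTM(Module):
    """Unidirectional LSTM over a (T, D) sequence; zero initial state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        h = n_hidden
        self.wx = Tensor(_uniform_init(rng, (n_in, 4 * h), n_in), requires_grad=True)
        self.wh = Tensor(_uniform_init(rng, (h, 4 * h), h), requires_grad=True)
        self.b = Tensor(_uniform_init(rng, (4 * h,), n_in), requires_grad=True)
        # forget-gate bias nudged positive for stable early training
        self.b.data[h : 2 * h] += 1.0
        self._params = [self.wx, self.wh, self.b]
        self.last_macs = 0.0
        self.last_adds = 0.0

    def forward(self, x: Tensor) -> Tensor:
        t_len = x.data.shape[0]
        h = self.n_hidden
        ht = Tensor(np.zeros((1, h)))
        ct = Tensor(np.zeros((1, h)))
        gx_all = matmul(x, self.wx) + self.b
        outs = []
        for t in range(t_len):
            g = gx_all[t : t + 1] + matmul(ht, self.wh)
            i = g[:, :h].sigmoid()
            f = g[:, h : 2 * h].sigmoid()
            o = g[:, 2 * h : 3 * h].sigmoid()
            c_tilde = g[:, 3 * h :].tanh()
            ct = f * ct + i * c_tilde
            ht = o * ct.tanh()
            outs.append(ht)
        self.last_macs = float(4 * (self.n_in * h + h * h) * t_len)
        self.last_adds = float(4 * h * t_len)
        return concat(outs, axis=0)
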