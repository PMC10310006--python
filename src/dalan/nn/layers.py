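"""Neural-network layers built on :mod:`dalan.nn.tensor`.

Includes the pieces the aggregation network needs: dense and convolutional
layers, 2x2 max pooling, stacked LSTMs with the standard four-gate cell,
and multi-head scaled dot-product attention (self- or co-attention).
Convolution uses ``sliding_window_view`` + one BLAS matmul per layer so the
whole stack runs at practical speed on a single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, stack

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "MaxPool2d", "ReLU",
    "Sequential", "LSTM", "MultiHeadAttention", "scaled_dot_attention",
]


def Parameter(data) -> Tensor:
    t = Tensor(data, requires_grad=True)
    return t


class Module:
    """Base class: parameter discovery, train/eval mode, freezing."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
                    elif isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution over (B, C, H, W) input, stride 1, 'same' padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.stride = stride
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        bound = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, bound, size=(out_channels, in_channels,
                                                             kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        w, b = self.weight, self.bias
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        B, C, Hp, Wp = xd.shape
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        view = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        out_data = np.einsum("bcyxij,ocij->boyx", view, w.data, optimize=True)
        out_data += b.data[None, :, None, None]

        def bw(g):
            if w.requires_grad:
                w._accumulate(np.einsum("boyx,bcyxij->ocij", g, view, optimize=True))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
                gt = g.transpose(0, 2, 3, 1)                 # B,Ho,Wo,Cout
                for di in range(k):                          # per-offset GEMM scatter
                    for dj in range(k):
                        contrib = gt @ w.data[:, :, di, dj]  # B,Ho,Wo,C
                        gxp[:, :, di:di + Ho * s:s, dj:dj + Wo * s:s] += \
                            contrib.transpose(0, 3, 1, 2)
                if p:
                    gxp = gxp[:, :, p:-p, p:-p]
                x._accumulate(gxp)

        return Tensor._make(out_data, (x, w, b), bw)


class MaxPool2d(Module):
    """Non-overlapping max pooling with square window (default 2x2)."""

    def __init__(self, window: int = 2):
        super().__init__()
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        wdw = self.window
        B, C, H, W = x.data.shape
        Ho, Wo = H // wdw, W // wdw
        xd = x.data[:, :, :Ho * wdw, :Wo * wdw]
        blocks = xd.reshape(B, C, Ho, wdw, Wo, wdw).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, wdw * wdw)
        arg = blocks.argmax(axis=-1)
        out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gb = np.zeros_like(blocks)
            np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
            gx = gb.reshape(B, C, Ho, Wo, wdw, wdw).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * wdw, Wo * wdw)
            if (Ho * wdw, Wo * wdw) != (H, W):
                full = np.zeros((B, C, H, W), dtype=np.float32)
                full[:, :, :Ho * wdw, :Wo * wdw] = gx
                gx = full
            x._accumulate(gx)

        return Tensor._make(out_data, (x,), bw)


class LSTM(Module):
    """Stacked LSTM over (B, N, D) sequences, returning all hidden states.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialised to 1 so early training keeps memory.
    """

    def __init__(self, input_dim: int, hidden_dim: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.w_x, self.w_h, self.b = [], [], []
        for layer in range(n_layers):
            d_in = input_dim if layer == 0 else hidden_dim
            bound = 1.0 / np.sqrt(hidden_dim)
            self.w_x.append(Parameter(rng.uniform(-bound, bound, size=(d_in, 4 * hidden_dim))))
            self.w_h.append(Parameter(rng.uniform(-bound, bound, size=(hidden_dim, 4 * hidden_dim))))
            bias = np.zeros(4 * hidden_dim, dtype=np.float32)
            bias[hidden_dim:2 * hidden_dim] = 1.0
            self.b.append(Parameter(bias))

    def forward(self, x: Tensor) -> Tensor:
        B, N, _ = x.shape
        H = self.hidden_dim
        seq = x
        for layer in range(self.n_layers):
            wx, wh, b = self.w_x[layer], self.w_h[layer], self.b[layer]
            # input projections for every timestep in one GEMM
            d_in = seq.shape[-1]
            xproj = seq.reshape(B * N, d_in) @ wx + b
            xproj = xproj.reshape(B, N, 4 * H)
            h = Tensor(np.zeros((B, H), dtype=np.float32))
            c = Tensor(np.zeros((B, H), dtype=np.float32))
            outs = []
            for t in range(N):
                gates = xproj[:, t, :] + h @ wh
                i = gates[:, 0 * H:1 * H].sigmoid()
                f = gates[:, 1 * H:2 * H].sigmoid()
                g = gates[:, 2 * H:3 * H].tanh()
                o = gates[:, 3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outs.append(h)
            seq = stack(outs, axis=1)
        return seq


def scaled_dot_attention(query: Tensor, key: Tensor, value: Tensor,
                         scale: str = "sqrt") -> tuple[Tensor, np.ndarray]:
    """softmax(Q K^T / s) V over the last two axes of batched sequences.

    ``scale='sqrt'`` divides scores by sqrt(d) (the standard choice);
    ``scale='linear'`` divides by d itself.  Returns (output, weights); the
    weight rows are a probability distribution over key positions.
    """
    if query.data.size == 0 or key.data.size == 0:
        raise ValueError("attention inputs must be non-empty")
    d = query.shape[-1]
    denom = float(np.sqrt(d)) if scale == "sqrt" else float(d)
    scores = (query @ key.swapaxes(-1, -2)) * (1.0 / denom)
    weights = scores.softmax(axis=-1)
    return weights @ value, weights.data


class MultiHeadAttention(Module):
    """Multi-head attention with per-head linear projections and output merge.

    Self-attention when query source equals the context; co-attention when the
    query comes from a different embedding stream.
    """

    def __init__(self, model_dim: int, n_heads: int, rng: np.random.Generator,
                 scale: str = "sqrt"):
        super().__init__()
        if model_dim % n_heads:
            raise ValueError(f"model_dim {model_dim} not divisible by n_heads {n_heads}")
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.head_dim = model_dim // n_heads
        self.scale = scale
        self.proj_q = Linear(model_dim, model_dim, rng)
        self.proj_k = Linear(model_dim, model_dim, rng)
        self.proj_v = Linear(model_dim, model_dim, rng)
        self.proj_out = Linear(model_dim, model_dim, rng)
        self.last_weights: np.ndarray | None = None   # (B, heads, Nq, Nk), inspection only

    def _split(self, t: Tensor) -> Tensor:
        B, N, D = t.shape
        return t.reshape(B, N, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x_query: Tensor, x_context: Tensor | None = None) -> Tensor:
        if x_context is None:
            x_context = x_query
        B, Nq, D = x_query.shape
        q = self._split(self.proj_q(x_query))
        k = self._split(self.proj_k(x_context))
        v = self._split(self.proj_v(x_context))
        out, w = scaled_dot_attention(q, k, v, scale=self.scale)
        self.last_weights = w
        merged = out.transpose(0, 2, 1, 3).reshape(B, Nq, D)
        return self.proj_out(merged)
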