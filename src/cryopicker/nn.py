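"""Neural-network building blocks on the in-package autodiff engine.

Layers follow the conventions of the detection-transformer family:
batch-first tensors ``(B, L, d)`` for sequences and ``(B, C, H, W)`` for
images, post-layer-norm residual blocks, additive dropout after attention
and feed-forward sublayers, Xavier-uniform initialization of projection
weights.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MultiheadAttention",
    "Embedding",
    "conv2d",
    "max_pool2d",
    "xavier_uniform_",
]


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable container tracking parameters, sub-modules and train mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []

        def visit(obj, path):
            if isinstance(obj, Parameter):
                out.append((path, obj))
            elif isinstance(obj, Module):
                out.extend(obj.named_parameters(path))
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    visit(item, f"{path}.{i}")

        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            visit(val, full)
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def xavier_uniform_(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    fan_out, fan_in = shape[0], shape[1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(xavier_uniform_((out_features, in_features), rng))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose() + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from the module's rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class MultiheadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads, batch-first."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, gated: bool = False):
        super().__init__()
        if d % n_heads:
            raise ValueError(f"hidden dim {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.out_proj = Linear(d, d, rng)
        # optional zero-initialized gate on the content scores: attention
        # starts at the additive prior alone and the learned q.k term is
        # admitted only as far as its gradient pulls the gate open (the
        # adaptive optimizer otherwise inflates the content scores at
        # lr-scale per step and destroys the prior before it can be used)
        self.score_gate = Parameter(np.zeros(1)) if gated else None

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        dk = self.d // self.n_heads
        return x.reshape(b, l, self.n_heads, dk).transpose(0, 2, 1, 3)

    def forward(
        self,
        query: Tensor,
        key: Tensor,
        value: Tensor,
        key_padding_mask: np.ndarray | None = None,
        attn_bias: np.ndarray | None = None,
    ) -> Tensor:
        b, lq, _ = query.shape
        dk = self.d // self.n_heads
        q = self._split(self.q_proj(query)) * (1.0 / math.sqrt(dk))
        k = self._split(self.k_proj(key))
        v = self._split(self.v_proj(value))
        scores = q @ k.transpose(0, 1, 3, 2)  # (B, H, Lq, Lk)
        if self.score_gate is not None:
            scores = scores * self.score_gate
        if attn_bias is not None:
            # additive logit prior, shared across heads; (Lq, Lk) applies to
            # the whole batch, (B, Lq, Lk) is per-item
            if attn_bias.ndim == 2:
                scores = scores + attn_bias[None, None, :, :]
            else:
                scores = scores + attn_bias[:, None, :, :]
        if key_padding_mask is not None:
            # True marks padded keys; a large negative bias removes them
            bias = np.where(key_padding_mask[:, None, None, :], -1e9, 0.0)
            scores = scores + bias
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, H, Lq, dk)
        out = out.transpose(0, 2, 1, 3).reshape(b, lq, self.d)
        return self.out_proj(out)


class Embedding(Module):
    """A table of ``n`` learned vectors of size ``d`` (used for slot queries).

    ``scale`` sets the init magnitude; slot queries use a small scale so the
    content embedding does not drown the image readout in the decoder's
    residual stream.
    """

    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 1.0):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, scale, size=(n, d)))

    def forward(self) -> Tensor:
        return self.weight


# ---------------------------------------------------------------------------
# convolution primitives (im2col formulation with hand-written backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, _, _ = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo, xp.shape


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW input, OIHW weight."""
    o, c, kh, kw = weight.shape
    cols, ho, wo, pad_shape = _im2col(x.data, kh, kw, stride, pad)
    w2 = weight.data.reshape(o, c * kh * kw)
    out = cols @ w2.T  # (N, Ho*Wo, O)
    if bias is not None:
        out = out + bias.data
    n = x.data.shape[0]
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, o)
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("nlo,nlk->ok", g2, cols)
            weight._accum(gw.reshape(o, c, kh, kw))
        if x.requires_grad:
            gcols = (g2 @ w2).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros(pad_shape)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            h0, w0 = x.data.shape[2], x.data.shape[3]
            x._accum(gxp[:, :, pad : pad + h0, pad : pad + w0])

    return Tensor._result(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, pad: int = 0) -> Tensor:
    n, c, _, _ = x.data.shape
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant", constant_values=-np.inf
    )
    view = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    ho, wo = view.shape[2], view.shape[3]
    flat = view.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gxp = np.zeros(xp.shape)
        ki, kj = np.divmod(idx, kernel)
        nn_, cc, ii, jj = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(ho), np.arange(wo), indexing="ij"
        )
        np.add.at(gxp, (nn_, cc, ii * stride + ki, jj * stride + kj), g)
        h0, w0 = x.data.shape[2], x.data.shape[3]
        x._accum(gxp[:, :, pad : pad + h0, pad : pad + w0])

    return Tensor._result(out, (x,), bw)
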