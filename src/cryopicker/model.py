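"""Query-based set-prediction detector for particle picking.

The detector has three parts:

* a convolutional **backbone** turning the (grayscale, replicated to three
  channels) micrograph into a C-channel activation map at 1/32 of the input
  resolution — a residual network (ResNet-50/152 layout, C=2048) at full
  scale, or a five-stage strided-conv ``tiny`` backbone (C=64) for
  desk-scale runs;
* an **encoder-decoder transformer**: a 1x1 convolution projects C down to
  the hidden size d, the spatial map is flattened to a sequence of H*W
  tokens, fixed 2-D sinusoidal positional encodings are added at the input
  of every self-attention layer, and N learned particle queries are decoded
  into N slot embeddings;
* **prediction heads**: per slot, a linear layer + softmax over
  {particle, ∅} and a 3-layer ReLU perceptron with a sigmoid output giving
  a normalized (cx, cy, w, h) box in [0, 1].

The output cardinality is always N, independent of how many particles the
micrograph holds; empty slots are claimed by the ∅ class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad
from . import nn

__all__ = [
    "ModelConfig",
    "FeatureMap",
    "PredictionSet",
    "SetPredictionDetector",
    "tiny_model_config",
    "sinusoidal_positions_2d",
]

_STRIDE = 32  # total spatial downsampling of every backbone


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``feature_channels`` defaults to the backbone's native width (2048 for
    the residual backbones, 64 for ``tiny``). ``n_queries`` bounds the
    number of particles a single micrograph can yield.
    """

    backbone_depth: str = "resnet152"
    feature_channels: int | None = None
    hidden_dim: int = 256
    n_queries: int = 600
    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    n_heads: int = 8
    dropout: float = 0.1
    ffn_dim: int | None = None  # defaults to 4 * hidden_dim

    def __post_init__(self):
        if self.backbone_depth not in {"tiny", "resnet50", "resnet152"}:
            raise ValueError(f"unknown backbone {self.backbone_depth!r}")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.n_queries < 1:
            raise ValueError("need at least one particle query")

    @property
    def channels(self) -> int:
        if self.feature_channels is not None:
            return self.feature_channels
        return 64 if self.backbone_depth == "tiny" else 2048

    @property
    def ffn_width(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim


def tiny_model_config(n_queries: int = 30, **overrides) -> ModelConfig:
    """Desk-scale profile: tiny backbone, d=64, 2+2 layers, 4 heads.

    Dropout is off in this profile: at a few hundred optimizer steps the
    regularization noise outweighs the faint particle signal and traps the
    model in an input-independent solution (the full-scale default keeps
    dropout 0.1).
    """
    kwargs = dict(
        backbone_depth="tiny",
        hidden_dim=64,
        n_queries=n_queries,
        n_encoder_layers=2,
        n_decoder_layers=2,
        n_heads=4,
        dropout=0.0,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@dataclass
class FeatureMap:
    """Backbone output: values (B, C, H, W) with H=W=input/32, plus the
    boolean mask of feature cells that cover only padding."""

    values: Tensor
    mask: np.ndarray  # (B, H, W), True = padded

    @property
    def shape(self):
        return self.values.shape


@dataclass
class PredictionSet:
    """The N slot predictions for one micrograph (eval-mode, plain arrays)."""

    boxes: np.ndarray  # (N, 4) cxcywh in [0, 1]
    class_probs: np.ndarray  # (N, 2), columns (particle, ∅)

    def __post_init__(self):
        if self.boxes.shape[0] != self.class_probs.shape[0]:
            raise ValueError("boxes and class_probs disagree on N")


# ---------------------------------------------------------------------------
# positional encoding
# ---------------------------------------------------------------------------

def sinusoidal_embed_yx(ys: np.ndarray, xs: np.ndarray, d: int, temperature: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of normalized (y, x) coordinates in [0, 1].

    Half the channels encode y, half x, each as interleaved sin/cos at
    geometrically spaced frequencies; coordinates are scaled to [0, 2*pi].
    Broadcasts over the leading shape of ``ys``/``xs``.
    """
    if d % 4:
        raise ValueError("positional encoding needs hidden_dim divisible by 4")
    half = d // 2
    n_freq = half // 2
    freqs = temperature ** (-np.arange(n_freq) / n_freq)

    def embed(coord):
        ang = np.asarray(coord)[..., None] * 2 * math.pi * freqs
        return np.stack([np.sin(ang), np.cos(ang)], axis=-1).reshape(*np.shape(coord), half)

    return np.concatenate([embed(ys), embed(xs)], axis=-1)


def sinusoidal_positions_2d(h: int, w: int, d: int, temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2-D sinusoidal positional encodings of the feature grid,
    shape (h*w, d); cell centers at ((i+0.5)/h, (j+0.5)/w)."""
    ys = (np.arange(h) + 0.5) / h
    xs = (np.arange(w) + 0.5) / w
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return sinusoidal_embed_yx(yy, xx, d, temperature).reshape(h * w, d)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class _ConvLayer(nn.Module):
    """Conv + bias. ``relu_gain`` switches from Xavier to He-style fan-in
    scaling (the sqrt(2) gain that keeps variance constant through a ReLU
    stack — without it a 5-deep ReLU cascade attenuates the signal ~30x and
    the backbone output drowns under the positional encodings)."""

    def __init__(self, c_in, c_out, k, stride, pad, rng, bias=True, relu_gain=False):
        super().__init__()
        fan_in, fan_out = c_in * k * k, c_out * k * k
        if relu_gain:
            limit = math.sqrt(2.0) * math.sqrt(3.0 / fan_in)
        else:
            limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.weight = nn.Parameter(rng.uniform(-limit, limit, size=(c_out, c_in, k, k)))
        self.bias = nn.Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        b = None
        if self.bias is not None:
            b = self.bias
        out = nn.conv2d(x, self.weight, None, stride=self.stride, pad=self.pad)
        if b is not None:
            out = out + b.reshape(1, -1, 1, 1)
        return out


class _ChannelAffine(nn.Module):
    """Per-channel scale and shift (the frozen-normalization stand-in used
    in place of batch statistics; identity at initialization)."""

    def __init__(self, c):
        super().__init__()
        self.scale = nn.Parameter(np.ones(c))
        self.shift = nn.Parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.scale.reshape(1, -1, 1, 1) + self.shift.reshape(1, -1, 1, 1)


class TinyBackbone(nn.Module):
    """Five 3x3 stride-2 conv+ReLU stages: /32 downsampling, 64 channels."""

    def __init__(self, rng, c_out: int = 64):
        super().__init__()
        widths = [3, 16, 32, 64, c_out, c_out]
        self.layers = [
            _ConvLayer(widths[i], widths[i + 1], 3, 2, 1, rng, relu_gain=True)
            for i in range(5)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        return x


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, c_in, width, stride, rng):
        super().__init__()
        c_out = width * self.expansion
        self.conv1 = _ConvLayer(c_in, width, 1, 1, 0, rng, bias=False, relu_gain=True)
        self.norm1 = _ChannelAffine(width)
        self.conv2 = _ConvLayer(width, width, 3, stride, 1, rng, bias=False, relu_gain=True)
        self.norm2 = _ChannelAffine(width)
        self.conv3 = _ConvLayer(width, c_out, 1, 1, 0, rng, bias=False)
        self.norm3 = _ChannelAffine(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = _ConvLayer(c_in, c_out, 1, stride, 0, rng, bias=False)
            self.down_norm = _ChannelAffine(c_out)

    def forward(self, x: Tensor) -> Tensor:
        out = self.norm1(self.conv1(x)).relu()
        out = self.norm2(self.conv2(out)).relu()
        out = self.norm3(self.conv3(out))
        shortcut = x if self.down is None else self.down_norm(self.down(x))
        return (out + shortcut).relu()


class ResNetBackbone(nn.Module):
    """Bottleneck residual network in the 50/152-layer layout, C=2048."""

    BLOCKS = {"resnet50": (3, 4, 6, 3), "resnet152": (3, 8, 36, 3)}

    def __init__(self, depth: str, rng):
        super().__init__()
        blocks = self.BLOCKS[depth]
        self.stem = _ConvLayer(3, 64, 7, 2, 3, rng, bias=False, relu_gain=True)
        self.stem_norm = _ChannelAffine(64)
        self.stages = []
        c_in = 64
        for stage_idx, (n_blocks, width) in enumerate(zip(blocks, (64, 128, 256, 512))):
            stage = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage_idx > 0) else 1
                stage.append(_Bottleneck(c_in, width, stride, rng))
                c_in = width * _Bottleneck.expansion
            self.stages.append(stage)
        self.out_channels = c_in

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_norm(self.stem(x)).relu()
        x = nn.max_pool2d(x, 3, 2, 1)
        for stage in self.stages:
            for block in stage:
                x = block(x)
        return x


# ---------------------------------------------------------------------------
# transformer
# ---------------------------------------------------------------------------

class _EncoderLayer(nn.Module):
    def __init__(self, d, n_heads, ffn_dim, dropout, rng, drop_rng):
        super().__init__()
        self.attn = nn.MultiheadAttention(d, n_heads, rng)
        self.lin1 = nn.Linear(d, ffn_dim, rng)
        self.lin2 = nn.Linear(ffn_dim, d, rng)
        self.norm1 = nn.LayerNorm(d)
        self.norm2 = nn.LayerNorm(d)
        self.drop1 = nn.Dropout(dropout, drop_rng)
        self.drop2 = nn.Dropout(dropout, drop_rng)
        self.drop_ffn = nn.Dropout(dropout, drop_rng)

    def forward(self, src: Tensor, pos: np.ndarray, key_padding_mask) -> Tensor:
        # positional encodings enter the full self-attention input (queries,
        # keys AND values): memory tokens must carry explicit position so the
        # decoder can regress coordinates even when particle appearances are
        # near-identical across the image
        x = src + pos
        attn_out = self.attn(x, x, x, key_padding_mask=key_padding_mask)
        src = self.norm1(src + self.drop1(attn_out))
        ffn_out = self.lin2(self.drop_ffn(self.lin1(src).relu()))
        return self.norm2(src + self.drop2(ffn_out))


class _DecoderLayer(nn.Module):
    def __init__(self, d, n_heads, ffn_dim, dropout, rng, drop_rng):
        super().__init__()
        self.self_attn = nn.MultiheadAttention(d, n_heads, rng)
        # cross-attention starts at the Gaussian locality prior (gated
        # content scores, see MultiheadAttention): each slot reads its own
        # anchor neighborhood from the first step and content-dependent
        # attention is phased in by the learned gate
        self.cross_attn = nn.MultiheadAttention(d, n_heads, rng, gated=True)
        self.lin1 = nn.Linear(d, ffn_dim, rng)
        self.lin2 = nn.Linear(ffn_dim, d, rng)
        self.norm1 = nn.LayerNorm(d)
        self.norm2 = nn.LayerNorm(d)
        self.norm3 = nn.LayerNorm(d)
        self.drop1 = nn.Dropout(dropout, drop_rng)
        self.drop2 = nn.Dropout(dropout, drop_rng)
        self.drop3 = nn.Dropout(dropout, drop_rng)
        self.drop_ffn = nn.Dropout(dropout, drop_rng)

    def forward(self, tgt, memory, query_pos, mem_pos, key_padding_mask, cross_bias=None) -> Tensor:
        q = tgt + query_pos
        sa = self.self_attn(q, q, tgt)
        tgt = self.norm1(tgt + self.drop1(sa))
        ca = self.cross_attn(
            tgt + query_pos, memory + mem_pos, memory,
            key_padding_mask=key_padding_mask, attn_bias=cross_bias,
        )
        tgt = self.norm2(tgt + self.drop2(ca))
        ffn_out = self.lin2(self.drop_ffn(self.lin1(tgt).relu()))
        return self.norm3(tgt + self.drop3(ffn_out))


class _BoxHead(nn.Module):
    """3-layer perceptron with ReLU hidden activations and sigmoid output.

    The raw MLP output is offset by the slot's learned reference box (in
    logit space) before the sigmoid: see ``query_anchor`` on the detector.
    """

    def __init__(self, d, rng):
        super().__init__()
        self.l1 = nn.Linear(d, d, rng)
        self.l2 = nn.Linear(d, d, rng)
        self.l3 = nn.Linear(d, 4, rng)

    def forward(self, x: Tensor, anchor_logits: Tensor) -> Tensor:
        raw = self.l3(self.l2(self.l1(x).relu()).relu())
        return (raw + anchor_logits).sigmoid()


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class SetPredictionDetector(nn.Module):
    """End-to-end picker: backbone -> transformer -> {class, box} heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng([seed, 0])
        self._dropout_rng = np.random.default_rng([seed, 1])
        if cfg.backbone_depth == "tiny":
            self.backbone = TinyBackbone(rng, cfg.channels)
        else:
            self.backbone = ResNetBackbone(cfg.backbone_depth, rng)
            if self.backbone.out_channels != cfg.channels:
                raise ValueError(
                    f"feature_channels {cfg.channels} does not match backbone "
                    f"({self.backbone.out_channels})"
                )
        d = cfg.hidden_dim
        self.input_proj = _ConvLayer(cfg.channels, d, 1, 1, 0, rng)
        self.encoder_layers = [
            _EncoderLayer(d, cfg.n_heads, cfg.ffn_width, cfg.dropout, rng, self._dropout_rng)
            for _ in range(cfg.n_encoder_layers)
        ]
        self.decoder_layers = [
            _DecoderLayer(d, cfg.n_heads, cfg.ffn_width, cfg.dropout, rng, self._dropout_rng)
            for _ in range(cfg.n_decoder_layers)
        ]
        self.decoder_norm = nn.LayerNorm(d)
        # each particle query has two learned per-slot parameters: a content
        # embedding (attention pathway) and a reference box in logit space
        # (spatial prior of the slot, initialized spread over the image so
        # slots specialize by region from the first step and bipartite
        # matching stays stable early in training)
        self.query_embed = nn.Embedding(cfg.n_queries, d, rng, scale=0.1)
        anchor_rng = np.random.default_rng([seed, 7])
        # reference boxes start on a regular grid (slightly jittered):
        # uniform coverage without the clumps of a random draw, so no two
        # slots start as interchangeable claimants of the same region
        side = int(math.ceil(math.sqrt(cfg.n_queries)))
        gy, gx = np.meshgrid(
            (np.arange(side) + 0.5) / side, (np.arange(side) + 0.5) / side, indexing="ij"
        )
        centers = np.column_stack([gx.ravel(), gy.ravel()])[: cfg.n_queries]  # (cx, cy)
        centers = centers + anchor_rng.uniform(-0.2, 0.2, size=centers.shape) / side
        centers = np.clip(centers, 0.02, 0.98)
        ref = np.concatenate([centers, np.full((cfg.n_queries, 2), 0.08)], axis=1)
        self.query_anchor = nn.Parameter(np.log(ref / (1.0 - ref)))
        self.class_head = nn.Linear(d, 2, rng)
        # bias the ∅ logit up at init: most slots are empty in any micrograph
        self.class_head.bias.data[:] = [0.0, 2.0]
        self.box_head = _BoxHead(d, rng)

    # -- stage 1: backbone ----------------------------------------------------
    def extract_features(self, images: np.ndarray, pixel_mask: np.ndarray | None = None) -> FeatureMap:
        """Backbone forward.

        ``images``: (B, H0, W0) grayscale batch (already zero-padded to a
        common size); replicated to 3 channels internally. ``pixel_mask``
        marks padded pixels (True = padding). Input sides must be at least
        32 px and are padded up to the next multiple of 32 so the /32
        feature grid is exact.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        b, h0, w0 = images.shape
        if min(h0, w0) < _STRIDE:
            raise ValueError(f"images must be at least {_STRIDE}x{_STRIDE}, got {h0}x{w0}")
        if pixel_mask is None:
            pixel_mask = np.zeros((b, h0, w0), dtype=bool)
        pad_h = (-h0) % _STRIDE
        pad_w = (-w0) % _STRIDE
        if pad_h or pad_w:
            images = np.pad(images, ((0, 0), (0, pad_h), (0, pad_w)))
            pixel_mask = np.pad(
                pixel_mask, ((0, 0), (0, pad_h), (0, pad_w)), constant_values=True
            )
        # per-image standardization over real (unpadded) pixels; padding
        # stays at 0 = the standardized mean, so it is genuinely neutral
        valid = ~pixel_mask
        flat = images.reshape(b, -1)
        vflat = valid.reshape(b, -1)
        means = np.array([f[v].mean() if v.any() else 0.0 for f, v in zip(flat, vflat)])
        sds = np.array([f[v].std() if v.any() else 1.0 for f, v in zip(flat, vflat)])
        sds[sds == 0] = 1.0
        images = (images - means[:, None, None]) / sds[:, None, None]
        images = np.where(valid, images, 0.0)
        x = Tensor(np.repeat(images[:, None, :, :], 3, axis=1))
        feats = self.backbone(x)
        _, _, fh, fw = feats.shape
        # a feature cell is padding iff every pixel in its 32x32 patch is
        cell = pixel_mask.reshape(b, fh, _STRIDE, fw, _STRIDE)
        feat_mask = cell.all(axis=(2, 4))
        return FeatureMap(values=feats, mask=feat_mask)

    # -- stage 2: encoder -----------------------------------------------------
    def encode(self, fmap: FeatureMap):
        """Project to d channels, flatten to H*W tokens, run the encoder.

        Returns (memory (B, HW, d), positional encodings (HW, d),
        key padding mask (B, HW), normalized cell centers (HW, 2) as (y, x)).
        """
        z0 = self.input_proj(fmap.values)  # (B, d, H, W)
        b, d, h, w = z0.shape
        seq = z0.reshape(b, d, h * w).transpose(0, 2, 1)  # (B, HW, d)
        pos = sinusoidal_positions_2d(h, w, d)
        yy, xx = np.meshgrid((np.arange(h) + 0.5) / h, (np.arange(w) + 0.5) / w, indexing="ij")
        grid = np.column_stack([yy.ravel(), xx.ravel()])
        mask = fmap.mask.reshape(b, h * w)
        memory = seq
        for layer in self.encoder_layers:
            memory = layer(memory, pos, mask)
        return memory, pos, mask, grid

    # -- stage 3: decoder + heads --------------------------------------------
    # width (in normalized units) of the Gaussian locality prior each slot's
    # cross-attention carries around its reference box; comparable to the
    # reference box scale so a slot reads the image in its own neighborhood
    CROSS_ATTN_SIGMA = 0.06

    def decode_and_predict(
        self,
        memory: Tensor,
        mem_pos: np.ndarray,
        mem_mask: np.ndarray,
        mem_grid: np.ndarray,
        return_aux: bool = False,
    ):
        """Decode the N particle queries; return (class_probs (B, N, 2),
        boxes (B, N, 4)).

        With ``return_aux`` (deep supervision during training) the shared
        heads are applied after every decoder layer and a list of
        per-layer (probs, boxes) pairs is returned, the last entry being
        the final prediction.
        """
        b = memory.shape[0]
        n, d = self.query_embed.weight.shape
        # the query's positional part is the sinusoidal embedding of its own
        # reference-box center (same code as the memory positions), so each
        # slot's cross-attention is focused near its anchor from the start;
        # the embedding is recomputed from the current anchors but treated
        # as a constant here (anchors learn through the box head)
        # the decoder input is the N learned content embeddings themselves
        # (never the zero vector: layer norm has a 1/sqrt(eps) Jacobian at
        # exactly zero input, which floods the dead self-attention path with
        # enormous gradients and starves every other parameter through the
        # gradient clip)
        tgt = self.query_embed.weight.reshape(1, n, d) + Tensor(np.zeros((b, n, d)))
        # iterative reference refinement: layer 1 reads around the slot's
        # learned reference box, predicts a box, and the next layer's
        # locality prior and positional code re-center on that estimate —
        # a coarse-to-fine read that recovers sub-cell localization
        centers = 1.0 / (1.0 + np.exp(-self.query_anchor.data[:, :2]))  # (N, 2) = (cx, cy)
        query_pos = Tensor(sinusoidal_embed_yx(centers[:, 1], centers[:, 0], d)[None])
        # spatially modulated cross-attention: a Gaussian logit prior centred
        # on each slot's reference box makes the readout local from the
        # first step
        dy = centers[:, 1][:, None] - mem_grid[None, :, 0]  # (N, HW)
        dx = centers[:, 0][:, None] - mem_grid[None, :, 1]
        cross_bias = -(dy**2 + dx**2) / (2.0 * self.CROSS_ATTN_SIGMA**2)
        anchor = self.query_anchor.reshape(1, n, 4)
        intermediate = []
        probs = boxes = None
        for layer in self.decoder_layers:
            tgt = layer(tgt, memory, query_pos, mem_pos, mem_mask, cross_bias=cross_bias)
            if return_aux:
                normed = self.decoder_norm(tgt)
                intermediate.append(
                    (self.class_head(normed).softmax(axis=-1), self.box_head(normed, anchor))
                )
        if return_aux:
            return intermediate
        tgt = self.decoder_norm(tgt)
        probs = self.class_head(tgt).softmax(axis=-1)
        boxes = self.box_head(tgt, anchor)
        return probs, boxes

    def forward(
        self, images: np.ndarray, pixel_mask: np.ndarray | None = None, return_aux: bool = False
    ):
        fmap = self.extract_features(images, pixel_mask)
        memory, pos, mask, grid = self.encode(fmap)
        return self.decode_and_predict(memory, pos, mask, grid, return_aux=return_aux)

    def predict(self, images: np.ndarray, pixel_mask: np.ndarray | None = None) -> list[PredictionSet]:
        """Eval-mode forward returning plain-array predictions per image."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs, boxes = self.forward(images, pixel_mask)
        finally:
            self.train(was_training)
        return [
            PredictionSet(boxes=boxes.data[i].copy(), class_probs=probs.data[i].copy())
            for i in range(probs.shape[0])
        ]
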