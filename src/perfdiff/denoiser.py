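"""Conditional U-Net noise predictor f(x, y_t, gamma).

The network takes the low-resolution conditioning image concatenated
channel-wise with the current noisy image (2 input channels), plus the
scalar noise level gamma, and predicts the injected noise (1 output
channel).  Structure: a multi-level encoder/decoder with residual blocks
(group normalization, SiLU, dropout), average-pool downsampling,
nearest-neighbour + convolution upsampling, skip connections at every
block, and single-head convolutional self-attention interleaved with the
residual blocks at the bottleneck.  The noise level enters through a
sinusoidal embedding of sqrt(gamma) refined by two linear layers and added
into every residual block as a per-channel bias.

The default configuration (five levels, channels [64, 128, 256, 512, 512],
two residual blocks per level) instantiates ~92M trainable parameters at a
96x96 input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["UNetConfig", "DenoiserModel", "build_denoiser", "predict_noise"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of the conditional U-Net."""

    levels: int = 5
    channels_per_level: tuple[int, ...] = (64, 128, 256, 512, 512)
    res_blocks_per_level: int = 2
    dropout: float = 0.2
    bottleneck_attention: bool = True
    gamma_embedding_dim: int | None = None   # defaults to channels_per_level[0]
    in_channels: int = 2
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.channels_per_level) != self.levels:
            raise ValueError("channels_per_level length must equal levels")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.res_blocks_per_level < 1:
            raise ValueError("need at least one residual block per level")
        if self.gamma_embedding_dim is None:
            object.__setattr__(self, "gamma_embedding_dim", self.channels_per_level[0])

    @property
    def size_divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "channels_per_level": list(self.channels_per_level),
            "res_blocks_per_level": self.res_blocks_per_level,
            "dropout": self.dropout,
            "bottleneck_attention": self.bottleneck_attention,
            "gamma_embedding_dim": self.gamma_embedding_dim,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        d = dict(d)
        d["channels_per_level"] = tuple(d["channels_per_level"])
        return cls(**d)

    @classmethod
    def desk(cls, seed: int = 0, dropout: float = 0.2) -> "UNetConfig":
        """Small preset for CPU-scale experiments on 32x32 images.

        One residual block per level: ample capacity for piecewise-constant
        phantom anatomy at a fraction of the full architecture's cost.
        """
        return cls(levels=3, channels_per_level=(16, 32, 64),
                   res_blocks_per_level=1, dropout=dropout, seed=seed)


def _norm_groups(channels: int, preferred: int = 32) -> int:
    for g in range(min(preferred, channels), 0, -1):
        if channels % g == 0:
            return g
    return 1


def _sinusoidal_embedding(level: np.ndarray, dim: int, scale: float = 1000.0) -> np.ndarray:
    """Transformer-style embedding of a continuous noise level."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    angles = (np.asarray(level, dtype=np.float64) * scale)[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb.astype(np.float32)


class DenoiserModel:
    """The parameterized noise-prediction network.

    Calling the model with plain arrays runs a deterministic evaluation-mode
    forward pass; :meth:`forward` exposes the differentiable path used by
    the trainer.
    """

    def __init__(self, config: UNetConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._decay: dict[str, bool] = {}
        self.training = False
        rng = np.random.default_rng(config.seed)
        self._build(rng)

    # -- parameter management ------------------------------------------------

    def _add(self, name: str, data: np.ndarray, decay: bool) -> Tensor:
        p = nn.parameter(data)
        self.params[name] = p
        self._decay[name] = decay
        return p

    def _conv(self, name: str, cin: int, cout: int, k: int, rng, gain: float = 1.0):
        w = nn.kaiming_normal((cout, cin, k, k), cin * k * k, rng, gain=gain)
        self._add(f"{name}.w", w, decay=True)
        self._add(f"{name}.b", np.zeros(cout, dtype=np.float32), decay=False)

    def _linear(self, name: str, cin: int, cout: int, rng, gain: float = 1.0):
        w = nn.kaiming_normal((cout, cin), cin, rng, gain=gain)
        self._add(f"{name}.w", w, decay=True)
        self._add(f"{name}.b", np.zeros(cout, dtype=np.float32), decay=False)

    def _gn(self, name: str, c: int):
        self._add(f"{name}.g", np.ones(c, dtype=np.float32), decay=False)
        self._add(f"{name}.b", np.zeros(c, dtype=np.float32), decay=False)

    def _resblock_params(self, name: str, cin: int, cout: int, emb_dim: int, rng):
        self._gn(f"{name}.gn1", cin)
        self._conv(f"{name}.conv1", cin, cout, 3, rng)
        self._linear(f"{name}.emb", emb_dim, cout, rng)
        self._gn(f"{name}.gn2", cout)
        # near-zero init of the second conv keeps fresh blocks close to identity
        self._conv(f"{name}.conv2", cout, cout, 3, rng, gain=1e-2)
        if cin != cout:
            self._conv(f"{name}.skip", cin, cout, 1, rng)

    def _attention_params(self, name: str, c: int, rng):
        self._gn(f"{name}.gn", c)
        for proj in ("q", "k", "v"):
            self._conv(f"{name}.{proj}", c, c, 1, rng)
        self._conv(f"{name}.out", c, c, 1, rng, gain=1e-2)

    def _build(self, rng) -> None:
        cfg = self.config
        chans = cfg.channels_per_level
        emb_hidden = 4 * cfg.gamma_embedding_dim
        self._linear("emb.l1", cfg.gamma_embedding_dim, emb_hidden, rng)
        self._linear("emb.l2", emb_hidden, emb_hidden, rng)
        self._conv("init", cfg.in_channels, chans[0], 3, rng)
        # encoder: skip channel bookkeeping mirrors the forward pass exactly
        self._skip_channels: list[int] = [chans[0]]
        cin = chans[0]
        for lvl, cout in enumerate(chans):
            for b in range(cfg.res_blocks_per_level):
                self._resblock_params(f"enc.{lvl}.{b}", cin, cout, emb_hidden, rng)
                cin = cout
                self._skip_channels.append(cout)
            if lvl < cfg.levels - 1:
                self._skip_channels.append(cout)     # post-pooling feature
        self._resblock_params("mid.rb1", cin, cin, emb_hidden, rng)
        if cfg.bottleneck_attention:
            self._attention_params("mid.attn", cin, rng)
        self._resblock_params("mid.rb2", cin, cin, emb_hidden, rng)
        skip_stack = list(self._skip_channels)
        for lvl in reversed(range(cfg.levels)):
            cout = chans[lvl]
            for b in range(cfg.res_blocks_per_level + 1):
                cskip = skip_stack.pop()
                self._resblock_params(f"dec.{lvl}.{b}", cin + cskip, cout, emb_hidden, rng)
                cin = cout
            if lvl > 0:
                self._conv(f"up.{lvl}", cin, cin, 3, rng)
        self._gn("final.gn", cin)
        self._conv("final.conv", cin, cfg.out_channels, 3, rng, gain=1e-2)

    @property
    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def decay_mask(self) -> list[bool]:
        return [self._decay[k] for k in self.params]

    def train(self) -> "DenoiserModel":
        self.training = True
        return self

    def eval(self) -> "DenoiserModel":
        self.training = False
        return self

    # -- forward pass --------------------------------------------------------

    def _resblock(self, name: str, x: Tensor, emb: Tensor,
                  rng: np.random.Generator | None) -> Tensor:
        p = self.params
        cin = x.shape[-1]
        h = nn.group_norm(x, p[f"{name}.gn1.g"], p[f"{name}.gn1.b"], _norm_groups(cin))
        h = nn.conv2d(nn.silu(h), p[f"{name}.conv1.w"], p[f"{name}.conv1.b"])
        bias = nn.linear(nn.silu(emb), p[f"{name}.emb.w"], p[f"{name}.emb.b"])
        h = nn.add(h, nn.reshape(bias, (bias.shape[0], 1, 1, bias.shape[1])))
        cout = h.shape[-1]
        h = nn.group_norm(h, p[f"{name}.gn2.g"], p[f"{name}.gn2.b"], _norm_groups(cout))
        h = nn.silu(h)
        if self.training and self.config.dropout > 0:
            h = nn.dropout(h, self.config.dropout, rng, training=True)
        h = nn.conv2d(h, p[f"{name}.conv2.w"], p[f"{name}.conv2.b"])
        if f"{name}.skip.w" in p:
            x = nn.conv2d(x, p[f"{name}.skip.w"], p[f"{name}.skip.b"], pad=0)
        return nn.add(h, x)

    def _attention(self, name: str, x: Tensor) -> Tensor:
        p = self.params
        b, hh, ww, c = x.shape
        h = nn.group_norm(x, p[f"{name}.gn.g"], p[f"{name}.gn.b"], _norm_groups(c))
        q = nn.conv2d(h, p[f"{name}.q.w"], p[f"{name}.q.b"], pad=0)
        k = nn.conv2d(h, p[f"{name}.k.w"], p[f"{name}.k.b"], pad=0)
        v = nn.conv2d(h, p[f"{name}.v.w"], p[f"{name}.v.b"], pad=0)
        hw = hh * ww
        q = nn.reshape(q, (b, hw, c))                                # (B, HW, C)
        k = nn.transpose(nn.reshape(k, (b, hw, c)), (0, 2, 1))       # (B, C, HW)
        v = nn.reshape(v, (b, hw, c))
        attn = nn.softmax(nn.scale(nn.matmul(q, k), 1.0 / np.sqrt(c)), axis=-1)
        out = nn.matmul(attn, v)                                     # (B, HW, C)
        out = nn.reshape(out, (b, hh, ww, c))
        out = nn.conv2d(out, p[f"{name}.out.w"], p[f"{name}.out.b"], pad=0)
        return nn.add(out, x)

    def forward(self, x: Tensor, gamma: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """Differentiable pass: ``x`` is (B, H, W, 2); gamma is (B,) in (0, 1]."""
        cfg = self.config
        b, hh, ww, cin_ = x.shape
        if cin_ != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {cin_}")
        d = cfg.size_divisor
        if hh % d or ww % d:
            raise ValueError(f"spatial size must be divisible by {d}")
        if self.training and self.config.dropout > 0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        p = self.params
        gamma = np.broadcast_to(np.asarray(gamma, dtype=np.float64), (b,))
        emb0 = Tensor(_sinusoidal_embedding(np.sqrt(gamma), cfg.gamma_embedding_dim))
        emb = nn.linear(emb0, p["emb.l1.w"], p["emb.l1.b"])
        emb = nn.linear(nn.silu(emb), p["emb.l2.w"], p["emb.l2.b"])
        h = nn.conv2d(x, p["init.w"], p["init.b"])
        skips = [h]
        for lvl in range(cfg.levels):
            for blk in range(cfg.res_blocks_per_level):
                h = self._resblock(f"enc.{lvl}.{blk}", h, emb, rng)
                skips.append(h)
            if lvl < cfg.levels - 1:
                h = nn.avg_pool2d(h)
                skips.append(h)
        h = self._resblock("mid.rb1", h, emb, rng)
        if cfg.bottleneck_attention:
            h = self._attention("mid.attn", h)
        h = self._resblock("mid.rb2", h, emb, rng)
        for lvl in reversed(range(cfg.levels)):
            for blk in range(cfg.res_blocks_per_level + 1):
                h = nn.concat([h, skips.pop()], axis=-1)
                h = self._resblock(f"dec.{lvl}.{blk}", h, emb, rng)
            if lvl > 0:
                h = nn.upsample_nearest2x(h)
                h = nn.conv2d(h, p[f"up.{lvl}.w"], p[f"up.{lvl}.b"])
        h = nn.group_norm(h, p["final.gn.g"], p["final.gn.b"], _norm_groups(h.shape[-1]))
        h = nn.conv2d(nn.silu(h), p["final.conv.w"], p["final.conv.b"])
        return h

    def __call__(self, x_lr: np.ndarray, y_t: np.ndarray, gamma) -> np.ndarray:
        """Evaluation-mode prediction on plain arrays.

        Accepts single images (H, W) or batches (B, H, W); the output matches
        the shape of ``y_t``.
        """
        return predict_noise(self, x_lr, y_t, gamma)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        with np.load(path) as z:
            cfg = UNetConfig.from_dict(json.loads(bytes(z["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = z[k].copy()
        return model


def build_denoiser(config: UNetConfig) -> DenoiserModel:
    """Instantiate the conditional U-Net described by ``config``."""
    return DenoiserModel(config)


def predict_noise(model: DenoiserModel, x_lr: np.ndarray, y_t: np.ndarray,
                  gamma) -> np.ndarray:
    """Predict the noise field for (batched or single) conditioned inputs."""
    x_lr = np.asarray(x_lr, dtype=np.float32)
    y_t = np.asarray(y_t, dtype=np.float32)
    if x_lr.shape != y_t.shape:
        raise ValueError("x_lr and y_t must share a shape")
    single = x_lr.ndim == 2
    if single:
        x_lr, y_t = x_lr[None], y_t[None]
    g = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    if np.any(g <= 0.0) or np.any(g > 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    stacked = Tensor(np.stack([x_lr, y_t], axis=-1))
    was_training = model.training
    model.training = False
    try:
        with nn.no_grad():
            out = model.forward(stacked, g)
    finally:
        model.training = was_training
    eps = out.data[..., 0]
    if not np.all(np.isfinite(eps)):
        raise FloatingPointError("non-finite noise prediction")
    return eps[0] if single else eps
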