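"""End-to-end blood-volume-pulse regressor.

Composition: the multi-scale difference stem converts a clip into per-frame
feature maps; refinement (SCOPE) blocks and stride-2 convolutional stages are
interleaved to shrink space and grow channels; per-frame global average
pooling produces one token per frame; a small pre-norm temporal transformer
(full self-attention over the D-frame token sequence, learned additive
position embeddings) models the quasi-periodic temporal structure; a linear
head reads out one wave sample per frame.

The temporal backbone is deliberately a plain transformer behind a narrow
interface (frame-feature sequence in, wave out), so alternative temporal
models can be swapped in without touching the stem or refinement blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as nnF
from .clipio import ClipBatch
from .mdfs import MDFSStem, StemConfig, multi_scale_difference
from .scope import SCOPE, ScopeConfig

__all__ = ["BackboneConfig", "ModelConfig", "RPPGNet", "build_model",
           "make_variant", "VARIANT_NAMES", "save_checkpoint", "load_checkpoint"]

VARIANT_NAMES = ("full", "no-SCOPE", "SCOPE-CBAM", "SCOPE-ChannelOnly",
                 "SCOPE-SpatialOnly", "SCOPE-NoGate", "MDFS-OriginalOnly",
                 "MDFS-Fixed")


@dataclass
class BackboneConfig:
    stages: int = 2          # stride-2 conv stages after the stem
    embed_dim: int = 96
    heads: int = 4
    depth: int = 4           # transformer blocks

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.stages < 0 or self.depth < 0:
            raise ValueError("stages and depth must be non-negative")


@dataclass
class ModelConfig:
    stem: StemConfig = field(default_factory=StemConfig)
    scope: ScopeConfig = field(default_factory=ScopeConfig)
    scope_insertions: int | None = None   # None -> one after stem + one per stage
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    clip_len: int = 160
    in_channels: int = 3
    token_norm: bool = True     # per-clip temporal standardization of tokens
    global_traces: bool = True  # append per-stream global color traces to tokens

    def n_scope(self) -> int:
        if self.scope_insertions is None:
            return self.backbone.stages + 1
        return self.scope_insertions

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["stem"] = StemConfig(**d.get("stem", {}))
        sc = dict(d.get("scope", {}))
        d["scope"] = ScopeConfig(**sc)
        d["backbone"] = BackboneConfig(**d.get("backbone", {}))
        return cls(**d)

    @classmethod
    def desk_preset(cls, d: int = 60) -> "ModelConfig":
        """Small configuration for 32x32 clips (development/CPU scale)."""
        return cls(stem=StemConfig(c_mid=16, dropout=0.1),
                   scope=ScopeConfig(reduction=8),
                   backbone=BackboneConfig(stages=2, embed_dim=96, heads=4, depth=4),
                   clip_len=d)

    @classmethod
    def paper_preset(cls) -> "ModelConfig":
        """Full-scale configuration: 128x128 inputs, 160-frame clips."""
        return cls(stem=StemConfig(c_mid=64), clip_len=160)


class RPPGNet(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        bb = config.backbone
        self.stem = MDFSStem(config.in_channels, config.stem, rng=rng)
        c = config.stem.c_mid
        n_scope = config.n_scope()

        self.scopes: list[nn.Module] = []
        self.stage_convs: list[nn.Module] = []
        self.stage_bns: list[nn.Module] = []
        if n_scope > 0:
            self.scopes.append(SCOPE(c, config.scope, rng=rng))
        for _ in range(bb.stages):
            c_next = c * 2
            self.stage_convs.append(nn.Conv2d(c, c_next, 3, stride=2, padding=1, rng=rng))
            self.stage_bns.append(nn.BatchNorm2d(c_next))
            c = c_next
            if len(self.scopes) < n_scope:
                self.scopes.append(SCOPE(c, config.scope, rng=rng))
        n_streams = 1 if config.stem.mode == "original_only" else \
            1 + len(config.stem.scales)
        self.token_dim = c + (config.in_channels * n_streams
                              if config.global_traces else 0)
        self.proj = nn.Linear(self.token_dim, bb.embed_dim, rng=rng)
        self.pos_embed = nn.Tensor(
            rng.normal(0, 0.02, (1, config.clip_len, bb.embed_dim)).astype(np.float32),
            requires_grad=True)
        self.blocks = [nn.TransformerBlock(bb.embed_dim, bb.heads, rng=rng)
                       for _ in range(bb.depth)]
        self.norm = nn.LayerNorm(bb.embed_dim)
        self.head = nn.Linear(bb.embed_dim, 1, rng=rng,
                              scale=1.0 / np.sqrt(bb.embed_dim))

    def forward(self, frames) -> nn.Tensor:
        """(N, D, C, H, W) pixels in [0, 1] -> (N, D) predicted pulse wave."""
        if isinstance(frames, ClipBatch):
            frames = frames.stack()
        frames = np.asarray(frames, np.float32)
        if frames.ndim == 4:
            frames = frames[None]
        n, d = frames.shape[:2]
        div = 4 * 2 ** self.config.backbone.stages
        if frames.shape[3] % div or frames.shape[4] % div:
            raise ValueError(
                f"spatial dims must be divisible by {div} for this configuration")
        x = self.stem(frames)                       # (N*D, c_mid, H/4, W/4)
        si = 0
        if si < len(self.scopes):
            x = self.scopes[si](x)
            si += 1
        for conv, bn in zip(self.stage_convs, self.stage_bns):
            x = bn(conv(x)).relu()
            if si < len(self.scopes):
                x = self.scopes[si](x)
                si += 1
        tokens = x.mean(axis=(2, 3)).reshape(n, d, -1)   # (N, D, C)
        if self.config.global_traces:
            # multi-scale global color traces: the per-frame spatial mean of
            # each stem input stream.  The whole-frame mean is a high-SNR,
            # translation-invariant carrier of the pulsatile color
            # modulation; difference-stream traces cancel static appearance
            # and slow illumination drift exactly as the stem streams do.
            tokens = nnF.concat([tokens, nn.Tensor(self._stream_traces(frames))],
                                axis=-1)
        if self.config.token_norm:
            # per-clip temporal standardization: static appearance carries no
            # temporal information, so each channel is centered and scaled
            # over the frame axis before temporal modelling — the subtle
            # pulsatile variation becomes the dominant token signal
            mu = tokens.mean(axis=1, keepdims=True)
            cen = tokens - mu
            sd2 = (cen * cen).mean(axis=1, keepdims=True)
            tokens = cen * ((sd2 + 1e-6) ** -0.5)
        tokens = self.proj(tokens)
        if d > self.pos_embed.shape[1]:
            raise ValueError(f"clip length {d} exceeds configured maximum "
                             f"{self.pos_embed.shape[1]}")
        tokens = tokens + self.pos_embed[:, :d]
        for blk in self.blocks:
            tokens = blk(tokens)
        wave = self.head(self.norm(tokens))         # (N, D, 1)
        return wave.reshape(n, d)

    def _stream_traces(self, frames: np.ndarray) -> np.ndarray:
        """(N, D, C * n_streams) spatial means of the stem's input streams."""
        if self.config.stem.mode == "original_only":
            streams = [frames]
        else:
            streams = multi_scale_difference(frames, self.config.stem.scales).streams
        return np.concatenate([s.mean(axis=(3, 4)) for s in streams], axis=-1)

    def predict(self, frames) -> np.ndarray:
        """Eval-mode forward returning a plain array (no graph)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(frames).data.copy()
        finally:
            self.train(was_training)
        return out

    def describe(self) -> str:
        cfg = self.config
        lines = [
            f"stem: mode={cfg.stem.mode}, c_mid={cfg.stem.c_mid}, "
            f"scales={cfg.stem.scales}, dropout={cfg.stem.dropout}",
            f"scope: variant={cfg.scope.variant} x{len(self.scopes)} insertions "
            f"(r={cfg.scope.reduction})",
            f"backbone: {cfg.backbone.stages} conv stages, transformer "
            f"depth={cfg.backbone.depth}, embed={cfg.backbone.embed_dim}, "
            f"heads={cfg.backbone.heads}",
            f"clip_len: {cfg.clip_len}",
            f"parameters: {self.num_parameters():,}",
        ]
        return "\n".join(lines)


def build_model(config: ModelConfig, seed: int = 0) -> RPPGNet:
    """Construct a seeded network; identical (config, seed) pairs give
    identical initial parameters."""
    return RPPGNet(config, seed=seed)


def make_variant(base: ModelConfig, name: str) -> ModelConfig:
    """Single-component ablation configs; everything else stays identical."""
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANT_NAMES}")
    if name == "full":
        return replace(base)
    if name == "no-SCOPE":
        return replace(base, scope_insertions=0)
    if name == "SCOPE-CBAM":
        return replace(base, scope=replace(base.scope, variant="cbam"))
    if name == "SCOPE-ChannelOnly":
        return replace(base, scope=replace(base.scope, variant="channel_only"))
    if name == "SCOPE-SpatialOnly":
        return replace(base, scope=replace(base.scope, variant="spatial_only"))
    if name == "SCOPE-NoGate":
        return replace(base, scope=replace(base.scope, variant="no_gate"))
    if name == "MDFS-OriginalOnly":
        return replace(base, stem=replace(base.stem, mode="original_only",
                                          fixed_weights=None))
    # MDFS-Fixed: all streams with uniform constant weights
    return replace(base, stem=replace(base.stem, mode="fixed", fixed_weights=None))


def save_checkpoint(path, model: RPPGNet) -> None:
    """NPZ checkpoint with the configuration embedded as JSON."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(Path(path), **state)


def load_checkpoint(path) -> RPPGNet:
    z = np.load(Path(path))
    cfg = ModelConfig.from_dict(json.loads(bytes(z["__config__"]).decode()))
    model = RPPGNet(cfg, seed=0)
    model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
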