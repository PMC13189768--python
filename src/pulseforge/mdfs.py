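"""Multi-scale Difference Fusion Stem (MDFS).

The stem converts a raw clip into four parallel streams — the original frames
X and the s-frame differences Δs for s in {1, 2, 3}, zero-padded over the
first s frames so all streams stay temporally aligned:

    Δs[t] = X[t] − X[t−s]   for t ≥ s,   Δs[t] = 0 for t < s.

Each stream passes through its own small convolutional branch (two stride-2
3x3 convolutions, C → C_mid → C_mid, so spatial dims shrink to H/4 x W/4),
is regularized by whole-channel dropout, and the four branch outputs are
fused by a softmax over four learnable logits:

    w_i = exp(δ_i) / Σ_j exp(δ_j),    out = ReLU(Σ_i w_i · f̃_i).

Differencing suppresses static appearance and exposes the faint pulsatile
modulation; learning the fusion lets the stem emphasize whichever temporal
scale carries the cleanest pulse under the current noise conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .clipio import FrameClip

__all__ = [
    "DiffStack", "StemConfig", "MDFSStem",
    "multi_scale_difference", "fusion_weights", "fuse_and_activate",
]

DEFAULT_SCALES = (1, 2, 3)


@dataclass
class DiffStack:
    """The parallel input streams (X, Δ1, Δ2, ...), each (..., D, C, H, W)."""

    streams: tuple[np.ndarray, ...]
    scales: tuple[int, ...]

    def __post_init__(self):
        shapes = {s.shape for s in self.streams}
        if len(shapes) != 1:
            raise ValueError(f"streams disagree in shape: {shapes}")


@dataclass
class StemConfig:
    c_mid: int = 64
    dropout: float = 0.1
    scales: tuple[int, ...] = DEFAULT_SCALES
    mode: str = "full"                       # full | original_only | fixed
    fixed_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        self.scales = tuple(self.scales)
        if self.mode not in ("full", "original_only", "fixed"):
            raise ValueError(f"unknown stem mode {self.mode!r}")
        if self.mode == "fixed":
            if self.fixed_weights is None:
                self.fixed_weights = tuple([1.0 / (len(self.scales) + 1)]
                                           * (len(self.scales) + 1))
            w = np.asarray(self.fixed_weights, dtype=np.float64)
            if w.size != len(self.scales) + 1:
                raise ValueError("fixed_weights must have one entry per stream")
            if abs(float(w.sum()) - 1.0) > 1e-6:
                raise ValueError(f"fixed weights must sum to 1, got {w.sum()}")


def multi_scale_difference(clip, scales=DEFAULT_SCALES) -> DiffStack:
    """Build the (X, Δs...) streams for one clip or a stacked batch.

    Accepts a :class:`FrameClip`, a (D, C, H, W) array, or an (N, D, C, H, W)
    array; the frame axis is the one differences run along.
    """
    x = clip.frames if isinstance(clip, FrameClip) else np.asarray(clip)
    t_axis = x.ndim - 4      # 0 for a single clip, 1 for a stacked batch
    d = x.shape[t_axis]
    scales = tuple(int(s) for s in scales)
    if any(s < 1 for s in scales):
        raise ValueError("difference scales must be positive")
    if scales and max(scales) >= d:
        raise ValueError(f"max scale {max(scales)} must be < clip length {d}")
    streams = [x.astype(np.float32, copy=True)]
    for s in scales:
        delta = np.zeros_like(streams[0])
        head = [slice(None)] * x.ndim
        tail = [slice(None)] * x.ndim
        head[t_axis] = slice(s, None)
        tail[t_axis] = slice(None, d - s)
        delta[tuple(head)] = streams[0][tuple(head)] - streams[0][tuple(tail)]
        streams.append(delta)
    return DiffStack(streams=tuple(streams), scales=scales)


def fusion_weights(logits) -> nn.Tensor:
    """Softmax weights over the fusion logits (max-subtracted, overflow-safe)."""
    t = logits if isinstance(logits, nn.Tensor) else nn.Tensor(np.asarray(logits))
    if not np.isfinite(t.data).all():
        raise ValueError("fusion logits must be finite")
    return t.softmax(axis=-1)


def fuse_and_activate(stream_features: list[nn.Tensor], weights: nn.Tensor) -> nn.Tensor:
    """ReLU of the convex combination of the branch features."""
    shapes = {f.shape for f in stream_features}
    if len(shapes) != 1:
        raise ValueError(f"stream features disagree in shape: {shapes}")
    if len(stream_features) != weights.shape[-1]:
        raise ValueError("one weight per stream is required")
    acc = stream_features[0] * weights[0]
    for i, f in enumerate(stream_features[1:], start=1):
        acc = acc + f * weights[i]
    return acc.relu()


class _Branch(nn.Module):
    """Per-stream projection: two stride-2 3x3 convs, C -> C_mid -> C_mid."""

    def __init__(self, c_in: int, c_mid: int, *, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_mid, 3, stride=2, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_mid)
        self.conv2 = nn.Conv2d(c_mid, c_mid, 3, stride=2, padding=1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv2(self.bn1(self.conv1(x)).relu())


class MDFSStem(nn.Module):
    """The full stem: difference streams -> branches -> dropout -> fusion.

    Modes:
      * ``full`` — learnable softmax fusion over all streams (the default);
      * ``original_only`` — only the raw-frame branch, no differencing;
      * ``fixed`` — all streams, fused with constant hand-set weights.
    """

    def __init__(self, c_in: int, config: StemConfig, *, rng: np.random.Generator):
        super().__init__()
        self.config = config
        n_streams = 1 if config.mode == "original_only" else 1 + len(config.scales)
        self.branches = [_Branch(c_in, config.c_mid, rng=rng) for _ in range(n_streams)]
        self.dropouts = [nn.Dropout2d(config.dropout, rng=rng) for _ in range(n_streams)]
        if config.mode == "full":
            self.fusion_logits = nn.Tensor(np.zeros(n_streams, np.float32),
                                           requires_grad=True)
        else:
            self.fusion_logits = None

    def forward(self, frames: np.ndarray) -> nn.Tensor:
        """``frames``: (N, D, C, H, W) in [0, 1] -> (N*D, C_mid, H/4, W/4)."""
        frames = np.asarray(frames, dtype=np.float32)
        if frames.ndim == 4:
            frames = frames[None]
        n, d, c, h, w = frames.shape
        if h % 4 or w % 4:
            raise ValueError(f"spatial dims must be divisible by 4, got {h}x{w}")
        cfg = self.config
        if cfg.mode == "original_only":
            streams = [frames]
        else:
            streams = list(multi_scale_difference(frames, cfg.scales).streams)
        feats = []
        for branch, drop, stream in zip(self.branches, self.dropouts, streams):
            f = branch(nn.Tensor(stream.reshape(n * d, c, h, w)))
            feats.append(drop(f))
        if cfg.mode == "original_only":
            return feats[0].relu()
        if cfg.mode == "fixed":
            w_fuse = nn.Tensor(np.asarray(cfg.fixed_weights, np.float32))
        else:
            w_fuse = fusion_weights(self.fusion_logits)
        return fuse_and_activate(feats, w_fuse)
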