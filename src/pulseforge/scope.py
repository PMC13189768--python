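"""Spatial-Channel Optimized Pulse Enhancement (SCOPE).

A frame-level refinement block for pulse-bearing feature maps, built from
three pieces applied to an input X of shape (B, C, Hm, Wm):

1. *Spatial-aware channel attention.*  X is viewed as B x (Hm·Wm) x C and a
   shared two-layer bottleneck MLP (C -> C/r -> C, sigmoid output) produces a
   channel weight vector independently at every spatial location:
   A_chan = σ(MLP(X_perm)), X_chan = X ⊙ A_chan.  Unlike pooling-based
   channel attention, different facial locations can emphasize different
   channels — pulse strength is spatially heterogeneous.
2. *Large-kernel spatial attention.*  Two consecutive channel-preserving 7x7
   convolutions with batch norm and ReLU give a per-channel spatial map:
   A_spa = ReLU(BN(Conv7(ReLU(BN(Conv7(X_chan)))))), X_spa = X_chan ⊙ A_spa.
3. *Adaptive gated residual fusion.*  A channel gate from global context,
   g = σ(Conv1x1(ReLU(Conv1x1(GAP(X_spa))))) ∈ (0,1)^{B x C x 1 x 1},
   modulates how much refinement is injected while the identity path is kept:
   X̂ = g ⊙ X_spa + X.

Ablation variants (single-component swaps) and a standard CBAM reference
block are provided for controlled comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["ScopeConfig", "SCOPE", "CBAMBlock", "VARIANTS"]

VARIANTS = ("full", "cbam", "channel_only", "spatial_only", "no_gate")


@dataclass
class ScopeConfig:
    reduction: int = 8
    variant: str = "full"
    spatial_sigmoid: bool = False   # optional terminal sigmoid on A_spa
    gate_input: str = "refined"     # "refined" (pool X_spa) or "input" (pool X)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown SCOPE variant {self.variant!r}")
        if self.gate_input not in ("refined", "input"):
            raise ValueError(f"unknown gate_input {self.gate_input!r}")


class _ChannelMLP(nn.Module):
    """Shared per-location bottleneck MLP with terminal sigmoid."""

    def __init__(self, c: int, r: int, *, rng: np.random.Generator):
        super().__init__()
        if c % r:
            raise ValueError(f"channel count {c} not divisible by reduction {r}")
        self.fc1 = nn.Linear(c, c // r, rng=rng)
        self.fc2 = nn.Linear(c // r, c, rng=rng)

    def forward(self, x_perm: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(x_perm).relu()).sigmoid()


class _SpatialConvs(nn.Module):
    def __init__(self, c: int, sigmoid: bool, *, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c, c, 7, padding=3, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 7, padding=3, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)
        self.sigmoid = sigmoid

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        a = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu())).relu()
        return a.sigmoid() if self.sigmoid else a


class _Gate(nn.Module):
    def __init__(self, c: int, r: int, *, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c, max(c // r, 1), 1, rng=rng)
        self.conv2 = nn.Conv2d(max(c // r, 1), c, 1, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv2(self.conv1(F.global_avg_pool(x)).relu()).sigmoid()


class SCOPE(nn.Module):
    """The refinement block; ``config.variant`` selects the ablation wiring.

    Variants:
      * ``full``         — X̂ = g ⊙ X_spa + X (both branches, gated)
      * ``no_gate``      — X̂ = X_spa + X
      * ``channel_only`` — X̂ = g ⊙ X_chan + X (gate fed by X_chan)
      * ``spatial_only`` — X̂ = g ⊙ X'_spa + X, spatial branch run on X itself
      * ``cbam``         — standard CBAM with the same outer residual
    """

    def __init__(self, c: int, config: ScopeConfig, *, rng: np.random.Generator):
        super().__init__()
        self.config = config
        v = config.variant
        r = config.reduction
        if v == "cbam":
            self.cbam = CBAMBlock(c, r, rng=rng)
            return
        if v in ("full", "channel_only", "no_gate"):
            self.channel_mlp = _ChannelMLP(c, r, rng=rng)
        if v in ("full", "spatial_only", "no_gate"):
            self.spatial = _SpatialConvs(c, config.spatial_sigmoid, rng=rng)
        if v in ("full", "channel_only", "spatial_only"):
            self.gate = _Gate(c, r, rng=rng)

    # -- submodule surfaces (exposed for tests and inspection) -----------

    def channel_attention(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        b, c, h, w = x.shape
        perm = x.reshape(b, c, h * w).transpose(0, 2, 1)       # B x (HW) x C
        a = self.channel_mlp(perm)
        a_chan = a.transpose(0, 2, 1).reshape(b, c, h, w)
        return a_chan, x * a_chan

    def spatial_attention(self, x_chan: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        a_spa = self.spatial(x_chan)
        return a_spa, x_chan * a_spa

    def gate_map(self, x: nn.Tensor) -> nn.Tensor:
        return self.gate(x)

    # ---------------------------------------------------------------------

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        v = self.config.variant
        if v == "cbam":
            return self.cbam(x)
        if v == "full":
            _, x_chan = self.channel_attention(x)
            _, x_spa = self.spatial_attention(x_chan)
            pooled_src = x_spa if self.config.gate_input == "refined" else x
            g = self.gate(pooled_src)
            return g * x_spa + x
        if v == "no_gate":
            _, x_chan = self.channel_attention(x)
            _, x_spa = self.spatial_attention(x_chan)
            return x_spa + x
        if v == "channel_only":
            _, x_chan = self.channel_attention(x)
            g = self.gate(x_chan if self.config.gate_input == "refined" else x)
            return g * x_chan + x
        # spatial_only: spatial branch runs directly on x
        _, x_spa = self.spatial_attention(x)
        g = self.gate(x_spa if self.config.gate_input == "refined" else x)
        return g * x_spa + x


class CBAMBlock(nn.Module):
    """Reference sequential channel-then-spatial attention block.

    Channel attention shares one bottleneck MLP over average- and max-pooled
    channel descriptors; spatial attention is a single 7x7 convolution over
    the channel-wise mean/max statistics.  The same outer residual as SCOPE
    is added so the block can be swapped in at identical insertion points.
    """

    def __init__(self, c: int, r: int = 8, kernel: int = 7, *,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(c, max(c // r, 1), bias=False, rng=rng)
        self.fc2 = nn.Linear(max(c // r, 1), c, bias=False, rng=rng)
        self.spatial_conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def _mlp(self, desc: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(desc).relu())

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, c, h, w = x.shape
        avg_desc = x.mean(axis=(2, 3))                 # B x C
        max_desc = x.reshape(b, c, h * w).max(axis=2)  # B x C
        mc = (self._mlp(avg_desc) + self._mlp(max_desc)).sigmoid()
        xc = x * mc.reshape(b, c, 1, 1)
        avg_map = xc.mean(axis=1, keepdims=True)
        max_map = xc.max(axis=1, keepdims=True)
        stats = _concat_channel(avg_map, max_map)
        ms = self.spatial_conv(stats).sigmoid()
        return xc * ms + x


def _concat_channel(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    """Concatenate two NCHW tensors along the channel axis."""
    data = np.concatenate([a.data, b.data], axis=1)
    ca = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return a._make(data, (a, b), backward)
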