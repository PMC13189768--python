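"""Module/parameter containers built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = [
    "Module", "Sequential", "Conv2d", "Linear", "BatchNorm2d", "LayerNorm",
    "Dropout2d", "ReLU", "Sigmoid", "Identity", "MultiHeadSelfAttention",
    "TransformerBlock",
]


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v.named_parameters(f"{key}.{i}."))
        return out

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        mods.extend(v.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, buf in self._named_buffers():
            buf[...] = state[name]

    def _named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value._named_buffers(key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        out.extend(v._named_buffers(f"{key}.{i}."))
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = _he_normal(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True, *,
                 rng: np.random.Generator, scale: float | None = None):
        super().__init__()
        std = scale if scale is not None else np.sqrt(2.0 / d_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm_2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout2d(Module):
    """Whole-channel dropout on NCHW maps with inverted (train-time) scaling.

    In training, each channel of each sample is zeroed with probability
    ``rate`` and survivors are scaled by 1/(1-rate); in eval the layer is the
    identity, so no rescaling is needed at inference.
    """

    def __init__(self, rate: float, *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.rate)
        mask = keep.astype(np.float32) / (1.0 - self.rate)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a token sequence.

    Input (B, T, E); heads split E. No masking: clips are short, fixed-length
    windows and the pulse is quasi-periodic, so bidirectional context is
    appropriate.
    """

    def __init__(self, embed_dim: int, heads: int, *, rng: np.random.Generator):
        super().__init__()
        if embed_dim % heads:
            raise ValueError("embed_dim must be divisible by heads")
        self.heads = heads
        self.dk = embed_dim // heads
        s = 1.0 / np.sqrt(embed_dim)
        self.qkv = Linear(embed_dim, 3 * embed_dim, rng=rng, scale=s)
        self.proj = Linear(embed_dim, embed_dim, rng=rng, scale=s)

    def forward(self, x: Tensor) -> Tensor:
        b, t, e = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.heads, self.dk)
        qkv = qkv.transpose(2, 0, 3, 1, 4)            # (3, B, H, T, dk)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block with an MLP ratio of 4."""

    def __init__(self, embed_dim: int, heads: int, *, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(embed_dim)
        self.attn = MultiHeadSelfAttention(embed_dim, heads, rng=rng)
        self.norm2 = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, 4 * embed_dim, rng=rng)
        self.fc2 = Linear(4 * embed_dim, embed_dim, rng=rng,
                          scale=1.0 / np.sqrt(4 * embed_dim))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).relu())
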