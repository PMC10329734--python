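"""Neural-network layers and optimization on top of :mod:`foldscreen.autograd`.

Conventions follow the common deep-learning layer contracts: convolutions
carry (out_channels, in_channels, kernel) weights with He initialization,
batch normalization keeps running statistics that are frozen in
evaluation mode, and the Adam optimizer uses the standard bias-corrected
moment estimates.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with parameter registration and train/eval switching."""

    def __init__(self):
        self._modules: Dict[str, "Module"] = {}
        self._params: Dict[str, Parameter] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Dict[str, Parameter]:
        out = {prefix + n: p for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.named_parameters(prefix + mn + "."))
        return out

    def named_buffers(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {prefix + n: b for n, b in self._buffers.items()}
        for mn, m in self._modules.items():
            out.update(m.named_buffers(prefix + mn + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters().items()}
        state.update({"buffer:" + k: b.copy() for k, b in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = self.named_parameters()
        for k, p in params.items():
            p.data[...] = state[k]
        buffers = self.named_buffers()
        for k in buffers:
            buffers[k][...] = state["buffer:" + k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return ag.conv1d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel),
                                         in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class Linear(Module):
    def __init__(self, in_f, out_f, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return ag.matmul(x, self.weight) + self.bias


class _BatchNorm(Module):
    """Shared batch-norm core; subclasses define the reduction axes."""

    axes: tuple

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def _shape(self, ndim):
        s = [1] * ndim
        s[1] = -1
        return tuple(s)

    def forward(self, x):
        shape = self._shape(x.ndim)
        gamma = ag.reshape(self.gamma, shape)
        beta = ag.reshape(self.beta, shape)
        if self.training:
            stats: list = []
            out = ag.batch_norm(x, gamma, beta, self.axes, self.eps,
                                stats_out=stats)
            mu, var = stats[0]
            n = x.data.size // x.data.shape[1]
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu.reshape(-1)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var.reshape(-1) * n / max(n - 1, 1)
            return out
        return ag.batch_norm(x, gamma, beta, self.axes, self.eps,
                             mean=self.running_mean.reshape(shape),
                             var=self.running_var.reshape(shape))


class BatchNorm1d(_BatchNorm):
    axes = (0, 2)


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = ag.tmean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = ag.tmean(centered * centered, axis=-1, keepdims=True)
        xhat = centered * ag.power(var + self.eps, -0.5)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, l in enumerate(layers):
            setattr(self, f"layer{i}", l)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x


class MultiHeadAttention(Module):
    """Multi-head softmax attention with relative key-query position term.

    Logits are ``(QW_q)(KW_k)^T / sqrt(d_k) + Q' R^T`` where ``R`` holds a
    learned embedding per relative offset (clipped at ``max_len``); weights of
    the last forward pass are kept per head for attribution.
    """

    def __init__(self, d_model, n_heads, max_len, rng=None):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        rng = rng or np.random.default_rng()
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.max_len = max_len
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.rel_emb = Parameter(rng.standard_normal(
            (n_heads, 2 * max_len - 1, self.d_head)).astype(DTYPE) * 0.02)
        self.last_weights: Optional[np.ndarray] = None

    def _split(self, x, L):
        # (N, L, D) -> (N, h, L, d_head)
        return ag.transpose(ag.reshape(x, (-1, L, self.n_heads, self.d_head)),
                            (0, 2, 1, 3))

    def forward(self, x):
        N, L, D = x.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds positional capacity {self.max_len}")
        q = self._split(self.wq(x), L)
        k = self._split(self.wk(x), L)
        v = self._split(self.wv(x), L)
        scale = 1.0 / math.sqrt(self.d_head)
        logits = ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))) * scale
        # relative key-query term: q_i . r_{j-i}
        offsets = np.arange(L)[None, :] - np.arange(L)[:, None]  # j - i
        idx = np.clip(offsets + self.max_len - 1, 0, 2 * self.max_len - 2)
        qe = ag.matmul(q, ag.transpose(self.rel_emb, (0, 2, 1)))  # (N,h,L,2M-1)
        logits = logits + ag.rel_gather(qe, idx) * scale
        weights = ag.softmax(logits, axis=-1)
        self.last_weights = weights.data.copy()
        out = ag.matmul(weights, v)  # (N,h,L,d_head)
        out = ag.reshape(ag.transpose(out, (0, 2, 1, 3)), (N, L, D))
        return self.wo(out)


class TransformerLayer(Module):
    """Post-norm attention block: MHA + residual + LN, FFN + residual + LN."""

    def __init__(self, d_model, n_heads, max_len, ffn_dim=None, rng=None):
        super().__init__()
        ffn_dim = ffn_dim or d_model
        self.attn = MultiHeadAttention(d_model, n_heads, max_len, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def forward(self, x):
        h = self.ln1(x + self.attn(x))
        return self.ln2(h + self.ff2(ag.relu(self.ff1(h))))


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: List[Parameter], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1c = 1 - self.b1 ** self.t
        b2c = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, epoch: float, period: float, floor: float = 0.0) -> float:
    """Cosine learning-rate schedule without restarts, floored at ``floor``."""
    return floor + 0.5 * (base_lr - floor) * (1 + math.cos(math.pi * (epoch % period) / period))
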