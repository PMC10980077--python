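"""Neural-network building blocks on top of the autodiff core.

Initialization follows common fan-based defaults (uniform ±1/sqrt(fan_in) for
linear layers, normal(0, 0.02) for embedding tables) and always draws from an
explicitly passed ``numpy.random.Generator`` so builds are reproducible.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor, einsum2, layer_norm, matmul, relu, softmax, take


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery and state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(out_dim,)))

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        out = matmul(flat, self.weight) + self.bias
        return out.reshape(*shape[:-1], self.weight.shape[1])


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_embeddings, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return take(self.weight, np.asarray(idx, dtype=int))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.eps) * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        if not train or self.p <= 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class RelativeMultiheadAttention(Module):
    """Multi-head self-attention with learned per-relative-distance key/value
    embeddings added during the attention calculation (Shaw-style).

    The ``n_classes``-row tables are per layer and shared across heads; each
    row is a head-dim-wide vector for one relative-distance bucket.  The
    integer bucket map ``dist_idx`` (L×L) is supplied at call time.
    """

    def __init__(self, embed_dim: int, n_heads: int, n_classes: int, rng):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.wq = Linear(embed_dim, embed_dim, rng)
        self.wk = Linear(embed_dim, embed_dim, rng)
        self.wv = Linear(embed_dim, embed_dim, rng)
        self.wo = Linear(embed_dim, embed_dim, rng)
        self.rel_k = Parameter(rng.normal(0.0, 0.02, size=(n_classes, self.head_dim)))
        self.rel_v = Parameter(rng.normal(0.0, 0.02, size=(n_classes, self.head_dim)))

    def __call__(self, x: Tensor, dist_idx: np.ndarray, collect_attn=None) -> Tensor:
        b, length, d = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(t):
            return t.reshape(b, length, h, hd).transpose(0, 2, 1, 3)  # (B,H,L,hd)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        rk = take(self.rel_k, dist_idx)  # (L,L,hd)
        rv = take(self.rel_v, dist_idx)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) + einsum2("bhid,ijd->bhij", q, rk)
        attn = softmax(scores * (1.0 / np.sqrt(hd)), axis=-1)
        if collect_attn is not None:
            collect_attn.append(attn.data.copy())
        out = matmul(attn, v) + einsum2("bhij,ijd->bhid", attn, rv)
        out = out.transpose(0, 2, 1, 3).reshape(b, length, d)
        return self.wo(out)


class EncoderLayer(Module):
    """Pre-layer-norm transformer encoder layer with ReLU feed-forward."""

    def __init__(self, embed_dim, n_heads, ff_dim, dropout, n_classes, rng):
        self.ln1 = LayerNorm(embed_dim)
        self.attn = RelativeMultiheadAttention(embed_dim, n_heads, n_classes, rng)
        self.drop1 = Dropout(dropout)
        self.ln2 = LayerNorm(embed_dim)
        self.ff1 = Linear(embed_dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, embed_dim, rng)
        self.drop_ff = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def __call__(self, x, dist_idx, train=False, rng=None, collect_attn=None):
        a = self.attn(self.ln1(x), dist_idx, collect_attn=collect_attn)
        x = x + self.drop1(a, train, rng)
        f = self.ff2(self.drop_ff(relu(self.ff1(self.ln2(x))), train, rng))
        return x + self.drop2(f, train, rng)
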