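"""Neural-network layers on top of the autograd engine.

Every layer draws its initial weights from the `numpy.random.Generator`
passed at construction, so a model built twice from the same seed is
bitwise identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    DTYPE,
    Tensor,
    batchnorm2d,
    conv1d,
    conv2d,
    embedding_lookup,
    layernorm,
    maxpool2x2,
    softmax,
)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, m in self._named_modules():
            for b_name, buf in getattr(m, "_buffers", {}).items():
                state[f"{m_name}{b_name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=DTYPE)
        for m_name, m in self._named_modules():
            for b_name in getattr(m, "_buffers", {}):
                key = f"{m_name}{b_name}"
                if key in state:
                    m._buffers[b_name] = np.array(state[key], dtype=DTYPE)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, d)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(d))
        self.shift = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layernorm(x, self.gain, self.shift, eps=self.eps)


class Dropout(Module):
    """Inverted dropout; the RNG is injected by the training loop."""

    def __init__(self, rate: float):
        super().__init__()
        assert 0.0 <= rate < 1.0
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0 or self.rng is None:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


def seed_dropout(root: Module, rng: np.random.Generator):
    for m in root.modules():
        if isinstance(m, Dropout):
            m.rng = rng


class MLP(Module):
    """Two-layer feed-forward block with ReLU, as inside a transformer layer."""

    def __init__(self, d: int, hidden: int, dropout: float, rng):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.fc1(x).relu()))


def _mask_bias(pad_mask: np.ndarray) -> np.ndarray:
    """Additive attention bias: -inf on padded key positions.

    A fully padded row would make softmax ill-defined, so position 0 is
    always left attendable (it carries the PAD embedding in that case).
    """
    mask = np.array(pad_mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[None, :]
    full = mask.all(axis=-1)
    if full.any():
        mask = mask.copy()
        mask[full, 0] = False
    bias = np.where(mask, -np.inf, 0.0)
    return bias[:, None, None, :]  # (B, 1 head, 1 query, L_key)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with H heads.

    Self-attention when `kv` is the same stream as `q`; cross-attention
    otherwise.  `key_pad_mask` (B, L_k) marks padded keys, which receive
    zero attention weight.
    """

    def __init__(self, d: int, n_heads: int, dropout: float, rng):
        super().__init__()
        if d % n_heads:
            raise ValueError(f"d_model={d} not divisible by n_heads={n_heads}")
        self.d = d
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.drop = Dropout(dropout)
        self.last_attn: np.ndarray | None = None  # (B, H, L_q, L_k), inspection only

    def __call__(self, q_in: Tensor, kv_in: Tensor, key_pad_mask=None) -> Tensor:
        B, Lq, d = q_in.shape
        Lk = kv_in.shape[1]
        H, dh = self.n_heads, self.d // self.n_heads

        def split(t, L):
            return t.reshape(B, L, H, dh).transpose((0, 2, 1, 3))

        q = split(self.wq(q_in), Lq)
        k = split(self.wk(kv_in), Lk)
        v = split(self.wv(kv_in), Lk)
        logits = (q @ k.swapaxes(-1, -2)) * (dh ** -0.5)
        if key_pad_mask is not None:
            logits = logits + Tensor(_mask_bias(key_pad_mask))
        attn = softmax(logits, axis=-1)
        self.last_attn = attn.data
        out = attn @ v  # (B, H, Lq, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(B, Lq, d)
        return self.drop(self.wo(out))


class EncoderBlock(Module):
    """Pre-norm self-attention block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, d, n_heads, mlp_ratio, dropout, rng):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadAttention(d, n_heads, dropout, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP(d, int(d * mlp_ratio), dropout, rng)

    def __call__(self, x: Tensor, pad_mask=None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, key_pad_mask=pad_mask)
        x = x + self.mlp(self.ln2(x))
        return x


class CrossBlock(Module):
    """Pre-norm cross-attention block between two token streams.

    Queries come from `stream` and keys/values from `other` by default;
    `query_source="other"` flips the projection sources while the output
    keeps `stream`'s length.
    """

    def __init__(self, d, n_heads, mlp_ratio, dropout, rng, query_source="self"):
        super().__init__()
        if query_source not in ("self", "other"):
            raise ValueError(f"bad query_source {query_source!r}")
        self.query_source = query_source
        self.ln_q = LayerNorm(d)
        self.ln_kv = LayerNorm(d)
        self.attn = MultiHeadAttention(d, n_heads, dropout, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP(d, int(d * mlp_ratio), dropout, rng)

    def __call__(self, stream: Tensor, other: Tensor,
                 other_pad_mask=None, stream_pad_mask=None) -> Tensor:
        if self.query_source == "self":
            q, kv, mask = self.ln_q(stream), self.ln_kv(other), other_pad_mask
        else:
            q, kv, mask = self.ln_q(other), self.ln_kv(stream), stream_pad_mask
            # output length must follow `stream`; only valid when lengths match
            if other.shape[1] != stream.shape[1]:
                raise ValueError(
                    "query_source='other' requires equal stream lengths")
        stream = stream + self.attn(q, kv, key_pad_mask=mask)
        stream = stream + self.mlp(self.ln2(stream))
        return stream


class Conv2dLayer(Module):
    def __init__(self, c_in, c_out, k, rng, padding=1, pad_mode="zeros"):
        super().__init__()
        bound = np.sqrt(6.0 / (c_in * k * k + c_out * k * k))
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = padding
        self.pad_mode = pad_mode

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      pad_mode=self.pad_mode)


class Conv1dLayer(Module):
    def __init__(self, c_in, c_out, k, rng, padding=1):
        super().__init__()
        bound = np.sqrt(6.0 / (c_in * k + c_out * k))
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(c))
        self.shift = Parameter(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(c, dtype=DTYPE),
            "running_var": np.ones(c, dtype=DTYPE),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm2d(x, self.gain, self.shift, eps=self.eps)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
            return out
        mu = Tensor(self._buffers["running_mean"][None, :, None, None])
        var = Tensor(self._buffers["running_var"][None, :, None, None])
        y = (x - mu) * ((var + self.eps) ** -0.5)
        return y * self.gain.reshape(1, -1, 1, 1) + self.shift.reshape(1, -1, 1, 1)


class MaxPool2x2(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)
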