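"""Neural layers for the pair transformer, built on the autodiff engine.

Linear layers use Kaiming (He) initialization; the encoder layer is the
pre-norm variant (residual branch splits before layer normalization) with
dropout on the attention and feed-forward sublayers and no positional
encoding.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal parameter container with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        if set(state) != set(params):
            raise ValueError("state dict does not match model parameters")
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=np.float64).copy()


def kaiming_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            kaiming_normal(rng, d_in, (d_in, d_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x) * self.gamma + self.beta


class PeriodicEmbedding(Module):
    """Per-feature periodic activation: x_i -> [sin(2 pi c_i x_i), cos(...)].

    ``coeffs`` holds one trainable length-k frequency vector per feature,
    initialized from N(0, sigma); no sharing across features.  Maps a batch
    (B, n) to (B, n, 2k).
    """

    def __init__(self, n_features: int, k: int, sigma: float, rng):
        super().__init__()
        if k < 1 or sigma <= 0:
            raise ValueError("need k >= 1 and sigma > 0")
        self.k = k
        self.coeffs = Tensor(
            rng.normal(0.0, sigma, size=(n_features, k)), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        B, n = x.shape
        if n != self.coeffs.shape[0]:
            raise ValueError(
                f"expected {self.coeffs.shape[0]} features, got {n}"
            )
        v = x.reshape(B, n, 1) * self.coeffs * (2.0 * np.pi)
        return ad.concat([ad.sin(v), ad.cos(v)], axis=-1)


class ContinuousEmbedding(Module):
    """Embed_c(x) = ReLU(Linear(Periodic(x))), one linear map per feature."""

    def __init__(self, n_features: int, k: int, sigma: float, d: int, rng):
        super().__init__()
        self.periodic = PeriodicEmbedding(n_features, k, sigma, rng)
        self.weight = Tensor(
            kaiming_normal(rng, 2 * k, (n_features, 2 * k, d)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros((n_features, d)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(ad.feature_linear(self.periodic(x), self.weight, self.bias))


class BinaryEmbedding(Module):
    """Per-feature lookup table of cardinality two: bit -> d-vector."""

    def __init__(self, n_features: int, d: int, rng):
        super().__init__()
        scale = 1.0 / np.sqrt(d)
        self.table0 = Tensor(
            rng.normal(0, scale, size=(n_features, d)), requires_grad=True
        )
        self.table1 = Tensor(
            rng.normal(0, scale, size=(n_features, d)), requires_grad=True
        )

    def __call__(self, bits: Tensor) -> Tensor:
        if not np.isin(bits.data, (0.0, 1.0)).all():
            raise ValueError("binary embedding input must be 0/1")
        B, m = bits.shape
        b = bits.reshape(B, m, 1)
        return self.table0 * (1.0 - b) + self.table1 * b


class MultiheadSelfAttention(Module):
    def __init__(self, d: int, heads: int, dropout: float, rng):
        super().__init__()
        if d % heads != 0:
            raise ValueError("embedding dimension must be divisible by heads")
        self.heads = heads
        self.d_head = d // heads
        self.dropout = dropout
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        B, T, d = x.shape
        H, dh = self.heads, self.d_head

        def split(t):
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)
        attn = ad.dropout(attn, self.dropout, rng, training)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d: int, d_ffn: int, dropout: float, rng):
        super().__init__()
        self.fc1 = Linear(d, d_ffn, rng)
        self.fc2 = Linear(d_ffn, d, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        h = ad.gelu(self.fc1(x))
        h = ad.dropout(h, self.dropout, rng, training)
        return self.fc2(h)


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer: x + Drop(Sub(LN(x))) twice."""

    def __init__(self, d: int, heads: int, d_ffn: int, dropout: float, rng):
        super().__init__()
        self.ln1 = LayerNorm(d)
        self.attn = MultiheadSelfAttention(d, heads, dropout, rng)
        self.ln2 = LayerNorm(d)
        self.ffn = FeedForward(d, d_ffn, dropout, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        x = x + ad.dropout(self.attn(self.ln1(x), rng, training), self.dropout, rng, training)
        x = x + ad.dropout(self.ffn(self.ln2(x), rng, training), self.dropout, rng, training)
        return x
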