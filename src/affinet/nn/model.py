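"""The pair transformer: a feature-tokenizer architecture for drug-target
affinity regression over four numerical descriptor blocks.

Continuous descriptors (compound physicochemical; protein Zernike + sequence)
enter through per-feature periodic embeddings, binary descriptors
(fingerprints; subfamily labels) through per-feature two-entry lookup tables.
Each stream (compound, protein) carries its own trainable CLS token, passes
through ``n_separate`` pre-norm encoder layers on its own, and the two token
matrices are then concatenated for ``n_joint`` joint layers.  The two
transformed CLS rows feed the prediction head

    yhat = Linear(ReLU(LayerNorm([CLS_c ; CLS_p]))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    BinaryEmbedding,
    ContinuousEmbedding,
    EncoderLayer,
    LayerNorm,
    Linear,
    Module,
)


@dataclass
class ModelConfig:
    d: int = 32  # token embedding dimension
    heads: int = 4
    n_separate: int = 2  # per-stream encoder layers
    n_joint: int = 2  # joint encoder layers
    d_ffn: int = 64
    k_periodic: int = 8  # periodic activation dimension
    sigma_periodic: float = 0.1  # frequency initialization scale
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.d % self.heads != 0:
            raise ValueError("d must be divisible by heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_joint < 1:
            raise ValueError("need at least one joint layer")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BlockDims:
    """Feature counts of the four input blocks of one pair."""

    compound_continuous: int
    compound_binary: int
    protein_continuous: int
    protein_binary: int

    def total(self) -> int:
        return (
            self.compound_continuous
            + self.compound_binary
            + self.protein_continuous
            + self.protein_binary
        )


class PairTransformer(Module):
    """Feature-tokenizer transformer over one compound-protein pair batch."""

    def __init__(self, dims: BlockDims, config: ModelConfig):
        super().__init__()
        self.dims = dims
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d

        if dims.compound_continuous:
            self.embed_cc = ContinuousEmbedding(
                dims.compound_continuous, config.k_periodic,
                config.sigma_periodic, d, rng,
            )
        if dims.compound_binary:
            self.embed_cb = BinaryEmbedding(dims.compound_binary, d, rng)
        if dims.protein_continuous:
            self.embed_pc = ContinuousEmbedding(
                dims.protein_continuous, config.k_periodic,
                config.sigma_periodic, d, rng,
            )
        if dims.protein_binary:
            self.embed_pb = BinaryEmbedding(dims.protein_binary, d, rng)

        self.cls_compound = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)
        self.cls_protein = Tensor(rng.normal(0, 0.02, size=d), requires_grad=True)

        mk = lambda: EncoderLayer(d, config.heads, config.d_ffn, config.dropout, rng)
        self.compound_layers = [mk() for _ in range(config.n_separate)]
        self.protein_layers = [mk() for _ in range(config.n_separate)]
        self.joint_layers = [mk() for _ in range(config.n_joint)]

        self.head_norm = LayerNorm(2 * d)
        self.head_linear = Linear(2 * d, 1, rng)

        self._dropout_rng = np.random.default_rng(config.seed + 1)

    def reseed_dropout(self, seed: int):
        self._dropout_rng = np.random.default_rng(seed)

    # ---- forward ------------------------------------------------------------

    def _tokens(self, x_cont, x_bin, embed_cont, embed_bin, cls, B):
        rows = []
        if x_cont is not None and x_cont.shape[1]:
            rows.append(embed_cont(x_cont))
        if x_bin is not None and x_bin.shape[1]:
            rows.append(embed_bin(x_bin))
        cls_row = cls.reshape(1, 1, self.config.d) * Tensor(
            np.ones((B, 1, 1))
        )
        rows.append(cls_row)
        return ad.concat(rows, axis=1) if len(rows) > 1 else rows[0]

    def forward(
        self,
        x_cc: np.ndarray,
        x_cb: np.ndarray,
        x_pc: np.ndarray,
        x_pb: np.ndarray,
        training: bool = False,
    ) -> Tensor:
        """Predict a (B,) affinity vector from the four descriptor blocks."""
        B = len(x_cc)
        rng = self._dropout_rng
        tc = self._tokens(
            Tensor(x_cc), Tensor(x_cb),
            getattr(self, "embed_cc", None), getattr(self, "embed_cb", None),
            self.cls_compound, B,
        )
        tp = self._tokens(
            Tensor(x_pc), Tensor(x_pb),
            getattr(self, "embed_pc", None), getattr(self, "embed_pb", None),
            self.cls_protein, B,
        )
        for layer in self.compound_layers:
            tc = layer(tc, rng, training)
        for layer in self.protein_layers:
            tp = layer(tp, rng, training)
        joint = ad.concat([tc, tp], axis=1)
        for layer in self.joint_layers:
            joint = layer(joint, rng, training)

        t_c = tc.shape[1]
        t_total = joint.shape[1]
        cls_c = ad.narrow(joint, 1, t_c - 1, 1).reshape(B, self.config.d)
        cls_p = ad.narrow(joint, 1, t_total - 1, 1).reshape(B, self.config.d)
        cls_pair = ad.concat([cls_c, cls_p], axis=-1)
        out = self.head_linear(ad.relu(self.head_norm(cls_pair)))
        return out.reshape(B)

    def predict(self, x_cc, x_cb, x_pc, x_pb) -> np.ndarray:
        """Deterministic eval-mode forward pass."""
        return self.forward(x_cc, x_cb, x_pc, x_pb, training=False).data
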