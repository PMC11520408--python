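"""High-level modelling surface: ``AffinityModel`` and ``AffinityResults``.

Follows the model/results convention of statistical modelling packages: an
``AffinityModel`` is constructed from a curated interaction table plus pair
features (optionally restricted by a selection signature), ``fit()`` runs the
training recipe (log-cosh loss, AdamW, early stopping, 5-best checkpoint
ensembling) and returns an ``AffinityResults`` carrying the ensemble, the
training log, holdout diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import PREDICTED_INACTIVITY_THRESHOLD, classify_activity
from .metrics import MetricsReport, evaluate
from .nn import (
    BlockDims,
    Ensemble,
    ModelConfig,
    PairTransformer,
    TrainConfig,
    train,
)
from .pairs import PairFeatures
from .selection import SelectionResult


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=X.mean(axis=0), sd=sd)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class AffinityModel:
    """Pair-transformer affinity regressor over one protein superfamily.

    Parameters
    ----------
    interactions
        Curated interaction table with ``compound_id``, ``protein_id`` and the
        label column named by ``label_type``.
    features
        ``PairFeatures`` aligned row-by-row with ``interactions``.
    label_type
        ``"pchembl"`` (affinity, -log10 molar) or ``"dtp_score"`` (in [0, 1]).
        One fitted model predicts exactly one label type.
    selection
        Optional ``SelectionResult``; restricts the descriptor columns to the
        selected signature (plus the always-kept subfamily labels).
    config
        Transformer architecture configuration.
    """

    def __init__(
        self,
        interactions: pd.DataFrame,
        features: PairFeatures,
        label_type: str = "pchembl",
        selection: SelectionResult | None = None,
        config: ModelConfig | None = None,
    ):
        if label_type not in ("pchembl", "dtp_score"):
            raise ValueError("label_type must be 'pchembl' or 'dtp_score'")
        if len(interactions) != len(features.compound_continuous):
            raise ValueError("interactions and features must align row-wise")
        self.interactions = interactions.reset_index(drop=True)
        self.label_type = label_type
        self.config = config or ModelConfig()
        self.y = self.interactions[label_type].to_numpy(dtype=float)

        if selection is not None:
            mask = features.layout.split_mask(selection.feature_indices)
            self._column_subsets = mask
            blocks = {
                "compound_continuous": features.compound_continuous[
                    :, mask["compound_continuous"]
                ],
                "compound_binary": features.compound_binary[
                    :, mask["compound_binary"]
                ],
                "protein_continuous": features.protein_continuous[
                    :, mask["protein_continuous"]
                ],
                "protein_binary": features.protein_binary[
                    :, mask["protein_binary"]
                ],
            }
        else:
            self._column_subsets = None
            blocks = {
                "compound_continuous": features.compound_continuous,
                "compound_binary": features.compound_binary,
                "protein_continuous": features.protein_continuous,
                "protein_binary": features.protein_binary,
            }
        self._blocks = blocks
        self.dims = BlockDims(
            compound_continuous=blocks["compound_continuous"].shape[1],
            compound_binary=blocks["compound_binary"].shape[1],
            protein_continuous=blocks["protein_continuous"].shape[1],
            protein_binary=blocks["protein_binary"].shape[1],
        )

    @classmethod
    def from_dataframe(
        cls,
        interactions: pd.DataFrame,
        features: PairFeatures,
        **kwargs,
    ) -> "AffinityModel":
        return cls(interactions, features, **kwargs)

    # -------------------------------------------------------------------------

    def _inputs(self, idx: np.ndarray, scalers) -> tuple:
        b = self._blocks
        return (
            scalers["cc"](b["compound_continuous"][idx]),
            b["compound_binary"][idx],
            scalers["pc"](b["protein_continuous"][idx]),
            b["protein_binary"][idx],
        )

    def fit(
        self,
        train_config: TrainConfig | None = None,
        holdout_fraction: float = 0.2,
        holdout_indices: np.ndarray | None = None,
    ) -> "AffinityResults":
        """Train the transformer and return the fitted results object.

        Continuous blocks are standardized on the training rows only; the
        holdout rows drive early stopping and checkpoint ranking.
        """
        cfg = train_config or TrainConfig(label_type=self.label_type)
        n = len(self.y)
        rng = np.random.default_rng(cfg.seed)
        if holdout_indices is None:
            n_hold = max(1, int(round(holdout_fraction * n)))
            perm = rng.permutation(n)
            holdout_indices = perm[:n_hold]
        holdout_indices = np.asarray(holdout_indices)
        train_indices = np.setdiff1d(np.arange(n), holdout_indices)

        scalers = {
            "cc": _Standardizer.fit(
                self._blocks["compound_continuous"][train_indices]
            ),
            "pc": _Standardizer.fit(
                self._blocks["protein_continuous"][train_indices]
            ),
        }
        net = PairTransformer(self.dims, self.config)
        train_tuple = (*self._inputs(train_indices, scalers), self.y[train_indices])
        hold_tuple = (*self._inputs(holdout_indices, scalers), self.y[holdout_indices])
        ensemble, log = train(net, train_tuple, hold_tuple, cfg)

        holdout_pred = ensemble.predict(net, *hold_tuple[:4])
        reports = evaluate(self.y[holdout_indices], holdout_pred)
        return AffinityResults(
            model=self,
            network=net,
            ensemble=ensemble,
            scalers=scalers,
            log=log,
            train_indices=train_indices,
            holdout_indices=holdout_indices,
            holdout_report=reports[0],
        )


@dataclass
class AffinityResults:
    """Fitted state: checkpoint ensemble, training log and diagnostics."""

    model: AffinityModel
    network: PairTransformer
    ensemble: Ensemble
    scalers: dict
    log: list[dict]
    train_indices: np.ndarray
    holdout_indices: np.ndarray
    holdout_report: MetricsReport
    _: dict = field(default_factory=dict, repr=False)

    @property
    def n_epochs(self) -> int:
        return len(self.log)

    def predict(self, features: PairFeatures | tuple) -> np.ndarray:
        """Ensemble-mean predictions for new pairs.

        Accepts a ``PairFeatures`` (full layout; the stored selection mask is
        re-applied) or an already-subset 4-tuple of blocks.
        """
        if isinstance(features, PairFeatures):
            subs = self.model._column_subsets
            blocks = features.blocks()
            if subs is not None:
                names = [
                    "compound_continuous",
                    "compound_binary",
                    "protein_continuous",
                    "protein_binary",
                ]
                blocks = tuple(b[:, subs[n]] for b, n in zip(blocks, names))
        else:
            blocks = features
        x_cc, x_cb, x_pc, x_pb = blocks
        return self.ensemble.predict(
            self.network,
            self.scalers["cc"](x_cc),
            x_cb,
            self.scalers["pc"](x_pc),
            x_pb,
        )

    def predict_activity(self, features) -> pd.DataFrame:
        """Predictions plus the thresholded activity call (inactive <= 5.1).

        Only meaningful for pChEMBL-type models.
        """
        pred = self.predict(features)
        calls = [classify_activity(v, context="predicted") for v in pred]
        return pd.DataFrame({"prediction": pred, "activity_call": calls})

    def summary(self) -> str:
        r = self.holdout_report
        lines = [
            "Affinity pair-transformer results",
            "=" * 48,
            f"label type:          {self.model.label_type}",
            f"feature blocks:      cc={self.model.dims.compound_continuous} "
            f"cb={self.model.dims.compound_binary} "
            f"pc={self.model.dims.protein_continuous} "
            f"pb={self.model.dims.protein_binary}",
            f"n train / holdout:   {len(self.train_indices)} / {len(self.holdout_indices)}",
            f"epochs run:          {self.n_epochs}",
            f"ensemble size:       {len(self.ensemble.checkpoints)}",
            f"best holdout loss:   {self.ensemble.checkpoints[0].holdout_loss:.6f}",
            "-" * 48,
            f"holdout RMSE:        {r.rmse:.4f}" if r.rmse is not None else "holdout RMSE:        undefined",
            f"holdout Spearman:    {r.spearman:.4f}" if r.spearman is not None else "holdout Spearman:    undefined",
            f"holdout CI:          {r.ci:.4f}" if r.ci is not None else "holdout CI:          undefined",
            f"inactivity cutoff:   {PREDICTED_INACTIVITY_THRESHOLD} (predicted scale)",
        ]
        return "\n".join(lines)
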