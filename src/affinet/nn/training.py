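"""Training loop: log-cosh loss, AdamW, early stopping, per-epoch
checkpointing and 5-best-checkpoint ensembling."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import PairTransformer
from .optim import AdamW

ENSEMBLE_SIZE = 5
#: an epoch must beat the best holdout loss by at least this much to reset
#: the early-stopping counter
IMPROVEMENT_TOL = 1e-5


def logcosh_loss(y: np.ndarray | Tensor, yhat: np.ndarray | Tensor) -> float | Tensor:
    """Mean log(cosh(yhat - y)); differentiable when given Tensors."""
    ty = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    th = yhat if isinstance(yhat, Tensor) else Tensor(np.asarray(yhat, dtype=np.float64))
    if ty.data.shape != th.data.shape:
        raise ValueError("y and yhat must have equal shape")
    if not (np.isfinite(ty.data).all() and np.isfinite(th.data).all()):
        raise ValueError("loss inputs must be finite")
    out = ad.logcosh(th - ty).mean()
    if isinstance(y, Tensor) or isinstance(yhat, Tensor):
        return out
    return float(out.data)


@dataclass
class TrainConfig:
    max_epochs: int = 500
    patience: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    weight_decay: float = 1e-5
    label_type: str = "pchembl"  # or "dtp_score"
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.label_type not in ("pchembl", "dtp_score"):
            raise ValueError("label_type must be 'pchembl' or 'dtp_score'")


@dataclass
class Checkpoint:
    epoch: int
    holdout_loss: float
    state: dict[str, np.ndarray]

    def save(self, path: Path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state)
        path.with_suffix(".json").write_text(
            json.dumps({"epoch": self.epoch, "holdout_loss": self.holdout_loss})
        )

    @classmethod
    def load(cls, path: Path) -> "Checkpoint":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            state = {k: z[k] for k in z.files}
        return cls(meta["epoch"], meta["holdout_loss"], state)


@dataclass
class Ensemble:
    """The checkpoints with the lowest holdout losses, ascending."""

    checkpoints: list[Checkpoint] = field(default_factory=list)

    def __post_init__(self):
        self.checkpoints.sort(key=lambda c: c.holdout_loss)

    def predict(self, model: PairTransformer, x_cc, x_cb, x_pc, x_pb) -> np.ndarray:
        """Arithmetic mean of member predictions."""
        if not self.checkpoints:
            raise ValueError("cannot predict with an empty ensemble")
        preds = []
        for ckpt in self.checkpoints:
            model.load_state_dict(ckpt.state)
            preds.append(model.predict(x_cc, x_cb, x_pc, x_pb))
        return np.mean(preds, axis=0)


class TrainingDiverged(RuntimeError):
    pass


def train(
    model: PairTransformer,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    holdout_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[Ensemble, list[dict]]:
    """Optimize with AdamW; return the 5-best-checkpoint ensemble and a log.

    ``train_data``/``holdout_data`` are ``(x_cc, x_cb, x_pc, x_pb, y)``
    tuples.  One checkpoint is taken per epoch; training stops when the
    holdout loss has not improved (by more than IMPROVEMENT_TOL) for
    ``cfg.patience`` epochs, or at ``cfg.max_epochs``.
    """
    x_cc, x_cb, x_pc, x_pb, y = (np.asarray(a) for a in train_data)
    hx = tuple(np.asarray(a) for a in holdout_data)
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(int(rng.integers(2**31 - 1)))
    opt = AdamW(
        model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay
    )

    checkpoints: list[Checkpoint] = []
    log: list[dict] = []
    best = np.inf
    stale = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            pred = model.forward(
                x_cc[idx], x_cb[idx], x_pc[idx], x_pb[idx], training=True
            )
            loss = logcosh_loss(Tensor(y[idx]), pred)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n

        holdout_pred = model.predict(hx[0], hx[1], hx[2], hx[3])
        holdout_loss = logcosh_loss(hx[4], holdout_pred)
        checkpoints.append(
            Checkpoint(epoch=epoch, holdout_loss=holdout_loss,
                       state=model.state_dict())
        )
        checkpoints.sort(key=lambda c: c.holdout_loss)
        del checkpoints[ENSEMBLE_SIZE:]
        log.append(
            {"epoch": epoch, "train_loss": epoch_loss,
             "holdout_loss": holdout_loss}
        )
        if holdout_loss < best - IMPROVEMENT_TOL:
            best = holdout_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return Ensemble(checkpoints=checkpoints), log
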