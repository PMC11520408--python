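"""Regression evaluation metrics: RMSE, Spearman rank correlation and
concordance index (CI), plus grouped evaluation reports.

CI is the probability that a randomly drawn comparable pair (y_i > y_j) is
predicted in the correct order, with ties in the prediction counted half:

    CI = (1/Z) sum_{y_i > y_j} h(yhat_i - yhat_j),
    h(u) = 1 (u > 0), 0.5 (u = 0), 0 (u < 0),

where Z is the number of comparable pairs.  1.0 is perfect ranking, 0.5 is
random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedMetricError(ValueError):
    pass


def _validate(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("labels and predictions must be finite")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _validate(y, yhat)
    if len(y) < 1:
        raise UndefinedMetricError("rmse needs at least one point")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def spearman(y, yhat) -> float:
    """Spearman rank correlation (mid-rank Pearson; tie-aware)."""
    y, yhat = _validate(y, yhat)
    if len(y) < 2:
        raise UndefinedMetricError("spearman needs at least two points")
    if y.std() == 0 or yhat.std() == 0:
        raise UndefinedMetricError("spearman undefined for zero-variance input")
    return float(stats.spearmanr(y, yhat).statistic)


def concordance_index(y, yhat) -> float:
    """Tie-aware concordance index over all comparable label pairs.

    Computed from the pairwise comparison matrix; O(N^2) memory, fine at the
    evaluation sizes this package targets.
    """
    y, yhat = _validate(y, yhat)
    dy = y[:, None] - y[None, :]
    comparable = dy > 0  # ordered pairs (i, j) with y_i > y_j
    Z = int(comparable.sum())
    if Z == 0:
        raise UndefinedMetricError(
            "concordance index undefined: no pair with y_i > y_j"
        )
    dp = yhat[:, None] - yhat[None, :]
    h = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(h[comparable].sum() / Z)


@dataclass
class MetricsReport:
    n: int
    rmse: float | None
    spearman: float | None
    ci: float | None
    group: str = "all"

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "N": self.n,
            "rmse": self.rmse,
            "spearman": self.spearman,
            "ci": self.ci,
        }


def evaluate(
    y,
    yhat,
    group_by: np.ndarray | pd.Series | None = None,
) -> list[MetricsReport]:
    """All three metrics, optionally per group (scenario or superfamily).

    Groups where a metric is undefined report ``None`` for that metric rather
    than being dropped.
    """
    y, yhat = _validate(np.asarray(y), np.asarray(yhat))
    if group_by is None:
        groups = {"all": np.arange(len(y))}
    else:
        group_by = np.asarray(group_by)
        if len(group_by) != len(y):
            raise ValueError("group_by must match y in length")
        groups = {
            str(g): np.flatnonzero(group_by == g) for g in np.unique(group_by)
        }
    reports = []
    for name, idx in groups.items():
        if len(idx) == 0:
            reports.append(MetricsReport(0, None, None, None, group=name))
            continue

        def _try(fn):
            try:
                return fn(y[idx], yhat[idx])
            except UndefinedMetricError:
                return None

        reports.append(
            MetricsReport(
                n=len(idx),
                rmse=_try(rmse),
                spearman=_try(spearman),
                ci=_try(concordance_index),
                group=name,
            )
        )
    return reports


def report_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
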