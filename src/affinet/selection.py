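"""Descriptor signature selection: repeated LASSO with cross-validated penalty.

For each protein superfamily the concatenated compound+protein descriptor
vector (7719 candidates at full scale) is reduced to a fixed budget of 1000
descriptors.  One selection round fits a LASSO regression of the interaction
score on the standardized descriptors, choosing the penalty alpha on a
regularization path by 5-fold cross-validation, refitting at the chosen alpha
on the full subset and marking descriptors with nonzero coefficients as
selected.  The round is repeated (100 times at reference scale) with only the
CV fold assignment re-randomized; the final signature keeps the most
frequently selected descriptors.  Binary subfamily labels never enter the
selection pool and are always appended to the output feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

#: coefficients with |beta| above this are "nonzero" (selected)
COEF_TOL = 1e-12


@dataclass
class LassoConfig:
    keep: int = 1000
    repeats: int = 100
    cv_folds: int = 5
    n_alphas: int = 30
    alpha_grid: np.ndarray | None = None  # overrides the automatic path
    eps: float = 1e-3  # path length alpha_min / alpha_max
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.keep < 1:
            raise ValueError("keep must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class SelectionResult:
    """Signature of one superfamily: frequencies, mask and bypass labels."""

    frequency: np.ndarray  # per-candidate selection counts over repeats
    mean_abs_coef: np.ndarray  # mean |beta| over repeats (tie-break ranking)
    final_mask: np.ndarray  # sorted indices of the retained candidates
    always_kept: np.ndarray  # indices of subfamily-label columns (bypass)
    repeats: int
    alphas: list = field(default_factory=list)  # CV-chosen alpha per repeat

    @property
    def feature_indices(self) -> np.ndarray:
        """Final model feature set: selected descriptors + subfamily labels."""
        return np.concatenate([self.final_mask, self.always_kept])


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def lasso_cv_fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LassoConfig,
    fold_seed: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One selection round: CV-chosen alpha, selected indices, coefficients.

    ``X`` must already be standardized.  Returns ``(alpha, selected, beta)``
    where ``selected`` are column indices with |beta| > COEF_TOL after the
    full-data refit at the CV-optimal alpha.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.std() == 0:
        raise ValueError("labels have zero variance; LASSO fit is degenerate")
    if len(y) < cfg.cv_folds:
        raise ValueError("need at least cv_folds samples")
    folds = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=fold_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv = LassoCV(
            alphas=cfg.alpha_grid if cfg.alpha_grid is not None else cfg.n_alphas,
            eps=cfg.eps,
            cv=folds,
            max_iter=cfg.max_iter,
        ).fit(X, y)
        refit = Lasso(alpha=cv.alpha_, max_iter=cfg.max_iter).fit(X, y)
    beta = refit.coef_
    selected = np.flatnonzero(np.abs(beta) > COEF_TOL)
    return float(cv.alpha_), selected, beta


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LassoConfig,
    subfamily_indices: np.ndarray | None = None,
) -> SelectionResult:
    """Repeated LASSO selection; keep the ``cfg.keep`` most frequent columns.

    Only the CV fold assignment changes between repeats (seeds derived from
    ``cfg.seed``).  Ties in frequency are broken by larger mean |beta| over
    repeats, then by lower column index.  Columns listed in
    ``subfamily_indices`` are excluded from the pool and appended unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    subfam = (
        np.asarray(subfamily_indices, dtype=int)
        if subfamily_indices is not None
        else np.array([], dtype=int)
    )
    pool = np.setdiff1d(np.arange(p), subfam)
    Xp = _standardize(X[:, pool])

    keep = cfg.keep
    if len(pool) < keep:
        warnings.warn(
            f"only {len(pool)} candidate descriptors for a keep budget of "
            f"{keep}; retaining all"
        )
        keep = len(pool)

    rng = np.random.default_rng(cfg.seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=cfg.repeats)
    frequency = np.zeros(len(pool), dtype=int)
    abs_coef_sum = np.zeros(len(pool))
    alphas = []
    for r in range(cfg.repeats):
        alpha, selected, beta = lasso_cv_fit(Xp, y, cfg, int(fold_seeds[r]))
        frequency[selected] += 1
        abs_coef_sum += np.abs(beta)
        alphas.append(alpha)
    mean_abs = abs_coef_sum / cfg.repeats

    # rank: frequency desc, mean |beta| desc, column index asc
    order = np.lexsort((np.arange(len(pool)), -mean_abs, -frequency))
    top = np.sort(pool[order[:keep]])
    return SelectionResult(
        frequency=frequency,
        mean_abs_coef=mean_abs,
        final_mask=top,
        always_kept=subfam,
        repeats=cfg.repeats,
        alphas=alphas,
    )


def build_selection_subset(
    interactions,
    compound_phases: dict[str, str],
    superfamily: str | None = None,
):
    """Rows eligible for signature selection: approved / phase-III compounds.

    ``interactions`` is a curated DataFrame with interaction-score labels;
    ``compound_phases`` maps compound_id to a development-phase string
    ('approved', 'phase3', 'phase2', ...).  Returns the filtered DataFrame.
    """
    eligible = {"approved", "phase3"}
    df = interactions
    if superfamily is not None:
        df = df[df["superfamily"] == superfamily]
    mask = df["compound_id"].map(
        lambda c: compound_phases.get(c, "preclinical") in eligible
    )
    out = df.loc[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            "no approved or phase-III compounds in the selection subset"
        )
    return out
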