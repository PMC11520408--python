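"""Bioactivity-table curation, train/test splitting and cold-start scenarios.

Curation rules for pairwise compound-protein bioactivity tables carrying two
label columns (a pChEMBL value, i.e. -log10 molar potency, and a harmonized
interaction score in [0, 1]):

1. duplicate (compound, protein) pairs are aggregated by the median of each
   label column independently over its non-missing entries;
2. pairs occurring in both the active and inactive tables are removed from
   both;
3. inactive records with interaction score 0 but pChEMBL > 5 are removed as
   internally contradictory.

Activity calls: a measured pChEMBL <= 5.0 is inactive; for model predictions
the threshold is 5.1, absorbing regression outputs that land just above the
measured cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

MEASURED_INACTIVITY_THRESHOLD = 5.0
PREDICTED_INACTIVITY_THRESHOLD = 5.1
TEST_FRACTION = 0.2

PAIR_COLS = ["compound_id", "protein_id"]
LABEL_COLS = ["pchembl", "dtp_score"]


class Scenario(str, Enum):
    """Cold-start novelty of a validation pair relative to the training set."""

    IMPUTATION = "A"  # compound and protein both seen in training
    NEW_COMPOUND = "B"  # compound unseen, protein seen
    NEW_BOTH = "C"  # both unseen
    EXCLUDED = "excluded"  # compound seen, protein unseen


def aggregate_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate pairs to one row with per-column median labels.

    Non-label metadata (superfamily, source_doc, ...) is taken from the first
    occurrence of each pair.
    """
    if records.empty:
        return records.copy()
    agg = {c: "median" for c in LABEL_COLS if c in records.columns}
    for c in records.columns:
        if c not in agg and c not in PAIR_COLS:
            agg[c] = "first"
    out = records.groupby(PAIR_COLS, as_index=False, sort=False).agg(agg)
    return out[[c for c in records.columns]]


def filter_conflicts(
    active: pd.DataFrame, inactive: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cross-listed pairs from both tables and contradictory inactives.

    An inactive record with dtp_score == 0 but pchembl > 5 contradicts its
    own labels and is removed.
    """
    a_keys = set(map(tuple, active[PAIR_COLS].itertuples(index=False)))
    i_keys = set(map(tuple, inactive[PAIR_COLS].itertuples(index=False)))
    both = a_keys & i_keys

    def _not_in_both(df: pd.DataFrame) -> pd.DataFrame:
        mask = [
            tuple(t) not in both for t in df[PAIR_COLS].itertuples(index=False)
        ]
        return df.loc[mask].reset_index(drop=True)

    clean_active = _not_in_both(active)
    clean_inactive = _not_in_both(inactive)
    contradictory = (clean_inactive["dtp_score"] == 0) & (
        clean_inactive["pchembl"] > MEASURED_INACTIVITY_THRESHOLD
    )
    clean_inactive = clean_inactive.loc[~contradictory].reset_index(drop=True)
    return clean_active, clean_inactive


def classify_activity(pchembl: float, context: str = "measured") -> str:
    """'active' or 'inactive' call for a pChEMBL value.

    ``context`` is 'measured' (threshold 5.0) or 'predicted' (threshold 5.1).
    """
    if not np.isfinite(pchembl):
        raise ValueError("pchembl must be finite")
    if context == "measured":
        threshold = MEASURED_INACTIVITY_THRESHOLD
    elif context == "predicted":
        threshold = PREDICTED_INACTIVITY_THRESHOLD
    else:
        raise ValueError("context must be 'measured' or 'predicted'")
    return "inactive" if pchembl <= threshold else "active"


def curate(
    records: pd.DataFrame, inactive: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Full curation: median aggregation then conflict filtering.

    When ``inactive`` is None the active/inactive partition is taken from the
    ``activity_flag`` column if present, otherwise from the measured pChEMBL
    threshold.
    """
    if inactive is None:
        if "activity_flag" in records.columns:
            is_inactive = records["activity_flag"] == "inactive"
        else:
            is_inactive = records["pchembl"] <= MEASURED_INACTIVITY_THRESHOLD
        active, inactive = records[~is_inactive], records[is_inactive]
    else:
        active = records
    active = aggregate_duplicates(active)
    inactive = aggregate_duplicates(inactive)
    clean_a, clean_i = filter_conflicts(active, inactive)
    out = pd.concat([clean_a, clean_i], ignore_index=True)
    # aggregation can itself produce a score-0/potent contradiction; the
    # curated table must be free of them regardless of provenance
    contradictory = (out["dtp_score"] == 0) & (
        out["pchembl"] > MEASURED_INACTIVITY_THRESHOLD
    )
    out = out.loc[~contradictory].reset_index(drop=True)
    assert not out.duplicated(PAIR_COLS).any()
    return out


@dataclass
class SplitSpec:
    """Per-superfamily train/test pair assignment (reproducible from seed)."""

    seed: int
    test_fraction: float = TEST_FRACTION
    train: pd.DataFrame = field(default_factory=pd.DataFrame)
    test: pd.DataFrame = field(default_factory=pd.DataFrame)


def split_train_test(
    dataset: pd.DataFrame,
    seed: int,
    test_fraction: float = TEST_FRACTION,
    by: str = "superfamily",
) -> SplitSpec:
    """Uniform random test split of ``test_fraction`` within each superfamily.

    The test count per group is round-to-nearest of fraction * group size.
    """
    rng = np.random.default_rng(seed)
    groups = dataset.groupby(by, sort=True) if by in dataset.columns else [
        ("all", dataset)
    ]
    train_parts, test_parts = [], []
    for name, group in groups:
        n = len(group)
        if n < 5:
            raise ValueError(
                f"superfamily {name!r} has only {n} records; need >= 5 to split"
            )
        n_test = int(round(test_fraction * n))
        perm = rng.permutation(n)
        test_parts.append(group.iloc[perm[:n_test]])
        train_parts.append(group.iloc[perm[n_test:]])
    spec = SplitSpec(seed=seed, test_fraction=test_fraction)
    spec.train = pd.concat(train_parts).reset_index(drop=True)
    spec.test = pd.concat(test_parts).reset_index(drop=True)
    return spec


def assign_validation_scenarios(
    train_pairs: pd.DataFrame, validation_pairs: pd.DataFrame
) -> pd.Series:
    """Label each validation pair with its cold-start scenario.

    A: both compound and protein occur in training; B: new compound, seen
    protein; C: both new.  The remaining case (seen compound, new protein) is
    excluded from evaluation.
    """
    seen_c = set(train_pairs["compound_id"])
    seen_p = set(train_pairs["protein_id"])

    def label(row) -> str:
        c_seen = row["compound_id"] in seen_c
        p_seen = row["protein_id"] in seen_p
        if c_seen and p_seen:
            return Scenario.IMPUTATION.value
        if not c_seen and p_seen:
            return Scenario.NEW_COMPOUND.value
        if not c_seen and not p_seen:
            return Scenario.NEW_BOTH.value
        return Scenario.EXCLUDED.value

    return validation_pairs.apply(label, axis=1)
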