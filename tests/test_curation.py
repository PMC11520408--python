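import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from affinet.curation import (
    Scenario,
    aggregate_duplicates,
    assign_validation_scenarios,
    classify_activity,
    curate,
    filter_conflicts,
    split_train_test,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "protein_id", "pchembl", "dtp_score"]
    )


class TestAggregateDuplicates:
    def test_odd_count_median(self):
        t = _table([("c", "p", 5.0, 0.1), ("c", "p", 6.0, 0.2), ("c", "p", 7.0, 0.9)])
        out = aggregate_duplicates(t)
        assert len(out) == 1
        assert out.loc[0, "pchembl"] == 6.0

    def test_even_count_median_is_midpoint(self):
        t = _table([("c", "p", 5.0, 0.2), ("c", "p", 7.0, 0.4)])
        out = aggregate_duplicates(t)
        assert out.loc[0, "pchembl"] == 6.0
        assert out.loc[0, "dtp_score"] == pytest.approx(0.3)

    def test_single_record_unchanged(self):
        t = _table([("c", "p", 6.5, 0.8)])
        pd.testing.assert_frame_equal(aggregate_duplicates(t), t)

    def test_label_columns_aggregated_independently_over_missing(self):
        t = _table([("c", "p", 5.0, np.nan), ("c", "p", 7.0, 0.4)])
        out = aggregate_duplicates(t)
        assert out.loc[0, "pchembl"] == 6.0
        assert out.loc[0, "dtp_score"] == pytest.approx(0.4)


class TestFilterConflicts:
    def test_pair_in_both_sets_removed_from_both(self):
        active = _table([("x", "p", 7.0, 0.9), ("y", "p", 8.0, 0.8)])
        inactive = _table([("x", "p", 4.0, 0.0), ("z", "p", 3.0, 0.0)])
        ca, ci = filter_conflicts(active, inactive)
        assert list(ca["compound_id"]) == ["y"]
        assert list(ci["compound_id"]) == ["z"]

    def test_contradictory_inactive_dropped(self):
        inactive = _table([("a", "p", 6.2, 0.0), ("b", "p", 4.0, 0.0)])
        _, ci = filter_conflicts(_table([]), inactive)
        assert list(ci["compound_id"]) == ["b"]

    def test_inactive_below_threshold_kept(self):
        inactive = _table([("a", "p", 4.0, 0.0)])
        _, ci = filter_conflicts(_table([]), inactive)
        assert len(ci) == 1


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "pchembl,context,expected",
        [
            (5.0, "measured", "inactive"),
            (5.05, "measured", "active"),
            (5.05, "predicted", "inactive"),
            (5.1, "predicted", "inactive"),
            (5.2, "predicted", "active"),
            (8.0, "measured", "active"),
        ],
    )
    def test_thresholds(self, pchembl, context, expected):
        assert classify_activity(pchembl, context) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_activity(float("nan"))


pair_ids = st.tuples(
    st.integers(min_value=0, max_value=8), st.integers(min_value=0, max_value=3)
)


@settings(deadline=None, max_examples=30)
@given(
    entries=st.lists(
        st.tuples(
            pair_ids,
            st.floats(min_value=2, max_value=11),
            st.floats(min_value=0, max_value=1),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_curated_dataset_invariants_hold_for_adversarial_tables(entries):
    """After curation: no duplicate pairs, no active/inactive cross-listing,
    no record with dtp_score = 0 and pchembl > 5."""
    df = pd.DataFrame(
        [
            {
                "compound_id": f"c{c}",
                "protein_id": f"p{p}",
                "pchembl": pc,
                "dtp_score": sc,
                "activity_flag": "active" if (c + p) % 2 else "inactive",
            }
            for (c, p), pc, sc in entries
        ]
    )
    out = curate(df)
    assert not out.duplicated(["compound_id", "protein_id"]).any()
    assert not ((out["dtp_score"] == 0) & (out["pchembl"] > 5)).any()


class TestSplit:
    def _dataset(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in range(n)],
                "protein_id": [f"p{i % 7}" for i in range(n)],
                "pchembl": rng.uniform(2, 11, n),
                "dtp_score": rng.uniform(0, 1, n),
                "superfamily": "kinase",
            }
        )

    def test_exact_fraction(self):
        spec = split_train_test(self._dataset(100), seed=1)
        assert len(spec.test) == 20 and len(spec.train) == 80

    def test_rounding_to_nearest(self):
        spec = split_train_test(self._dataset(101), seed=1)
        assert len(spec.test) == 20  # round(20.2)

    def test_deterministic_and_disjoint(self):
        a = split_train_test(self._dataset(50), seed=9)
        b = split_train_test(self._dataset(50), seed=9)
        assert set(a.test["compound_id"]) == set(b.test["compound_id"])
        assert not set(a.test["compound_id"]) & set(a.train["compound_id"])

    def test_too_few_records(self):
        with pytest.raises(ValueError, match=">= 5"):
            split_train_test(self._dataset(3), seed=0)

    def test_label_distribution_preserved(self):
        """Random subsampling keeps train/test label distributions close."""
        spec = split_train_test(self._dataset(2000, seed=3), seed=3)
        ks = stats.ks_2samp(spec.train["pchembl"], spec.test["pchembl"])
        assert ks.pvalue > 0.01


class TestScenarios:
    def test_partition(self):
        train = pd.DataFrame(
            {"compound_id": ["c1", "c2"], "protein_id": ["p1", "p2"]}
        )
        val = pd.DataFrame(
            {
                "compound_id": ["c1", "c9", "c8", "c2"],
                "protein_id": ["p2", "p1", "p9", "p9"],
            }
        )
        labels = assign_validation_scenarios(train, val)
        assert list(labels) == [
            Scenario.IMPUTATION.value,
            Scenario.NEW_COMPOUND.value,
            Scenario.NEW_BOTH.value,
            Scenario.EXCLUDED.value,
        ]

    def test_every_pair_gets_exactly_one_label(self, rng):
        train = pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in rng.integers(0, 20, 50)],
                "protein_id": [f"p{i}" for i in rng.integers(0, 8, 50)],
            }
        )
        val = pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in rng.integers(0, 40, 80)],
                "protein_id": [f"p{i}" for i in rng.integers(0, 16, 80)],
            }
        )
        labels = assign_validation_scenarios(train, val)
        valid = {s.value for s in Scenario}
        assert len(labels) == 80
        assert set(labels) <= valid
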