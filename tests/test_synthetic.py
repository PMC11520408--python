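import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from affinet import synthetic
from affinet.curation import curate, filter_conflicts
from affinet.metrics import spearman
from affinet.proteins import parse_structure


class TestCompounds:
    def test_distinct_and_parseable(self):
        table = synthetic.gen_compounds(10, seed=1)
        assert len(table) == 10
        assert table["smiles"].nunique() == 10
        assert all(Chem.MolFromSmiles(s) is not None for s in table["smiles"])

    def test_reproducible_from_seed(self):
        a = synthetic.gen_compounds(8, seed=4)
        b = synthetic.gen_compounds(8, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_compounds_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_compounds(0, seed=0)


class TestStructures:
    def test_roundtrip_through_parser(self):
        coords = synthetic.gen_structure_coords(25, seed=2)
        cloud = parse_structure(synthetic.write_pdb(coords))
        assert len(cloud.coordinates) == 25
        np.testing.assert_allclose(cloud.coordinates, coords, atol=5e-4)

    def test_different_seeds_differ(self):
        a = synthetic.gen_structure_coords(10, seed=1)
        b = synthetic.gen_structure_coords(10, seed=2)
        assert not np.allclose(a, b)

    def test_rotation_matrix_is_proper(self):
        R = synthetic.random_rotation(seed=5)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            synthetic.gen_structure_coords(3, seed=0)


class TestInteractions:
    def _pairs_and_features(self, n=80, p=30, seed=0):
        rng = np.random.default_rng(seed)
        pairs = pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in range(n)],
                "protein_id": [f"p{i % 5}" for i in range(n)],
                "superfamily": "kinase",
            }
        )
        return pairs, rng.normal(size=(n, p))

    def _spec(self, p=30, seed=0, noise_sd=0.1):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(p, 5, replace=False))
        return synthetic.SignalSpec(
            informative_indices=idx,
            weights=rng.normal(size=5),
            noise_sd=noise_sd,
            seed=seed,
        )

    def test_clean_generation_needs_no_curation(self):
        pairs, X = self._pairs_and_features()
        table = synthetic.gen_interactions(X, pairs, self._spec())
        curated = curate(table)
        assert len(curated) == len(table)

    def test_injected_conflicts_are_countable_and_removed(self):
        pairs, X = self._pairs_and_features()
        table = synthetic.gen_interactions(
            X, pairs, self._spec(), conflict_rate=0.1
        )
        n_conflicts = int(round(0.1 * 80))
        flags = table.groupby(["compound_id", "protein_id"])["activity_flag"].nunique()
        assert (flags > 1).sum() == n_conflicts
        active = table[table["activity_flag"] == "active"]
        inactive = table[table["activity_flag"] == "inactive"]
        ca, ci = filter_conflicts(
            active.drop_duplicates(["compound_id", "protein_id"]),
            inactive.drop_duplicates(["compound_id", "protein_id"]),
        )
        assert len(ca) + len(ci) <= len(table) - n_conflicts

    def test_duplicates_injected_at_rate(self):
        pairs, X = self._pairs_and_features()
        table = synthetic.gen_interactions(
            X, pairs, self._spec(), duplicate_rate=0.25
        )
        assert len(table) == 80 + int(round(0.25 * 80))

    def test_latent_rank_correlation_with_labels(self):
        """At noise sd = 0.1 the planted latent orders the labels almost
        perfectly, so a correct pipeline can demonstrably learn it."""
        pairs, X = self._pairs_and_features(n=200, seed=3)
        spec = self._spec(seed=3, noise_sd=0.1)
        table = synthetic.gen_interactions(X, pairs, spec)
        key = {c: i for i, c in enumerate(pairs["compound_id"])}
        rows = [key[c] for c in table["compound_id"]]
        latent = X[rows][:, spec.informative_indices] @ spec.weights
        assert spearman(latent, table["pchembl"].to_numpy()) >= 0.95
        assert spearman(latent, table["dtp_score"].to_numpy()) >= 0.95

    def test_label_ranges(self):
        pairs, X = self._pairs_and_features()
        table = synthetic.gen_interactions(X, pairs, self._spec(noise_sd=2.0))
        assert table["dtp_score"].between(0, 1).all()
        assert table["pchembl"].between(2, 11).all()

    def test_noise_free_labels_exactly_linear(self):
        pairs, X = self._pairs_and_features(n=50, seed=9)
        spec = self._spec(seed=9, noise_sd=0.0)
        table = synthetic.gen_interactions(X, pairs, spec)
        latent = X[:, spec.informative_indices] @ spec.weights
        z = (latent - latent.mean()) / latent.std()
        key = {c: i for i, c in enumerate(pairs["compound_id"])}
        rows = [key[c] for c in table["compound_id"]]
        expected = np.clip(6.5 + 0.45 * 4.5 * z[rows], 2, 11)
        np.testing.assert_allclose(table["pchembl"].to_numpy(), expected, atol=1e-9)


class TestDesignMatrix:
    def test_snr_calibration(self):
        X, y, spec = synthetic.gen_design_matrix(2000, 50, 5, 5.0, seed=0)
        signal = X[:, spec.informative_indices] @ spec.weights
        noise = y - signal
        assert signal.var() / noise.var() == pytest.approx(5.0, rel=0.2)

    def test_reproducible(self):
        a = synthetic.gen_design_matrix(50, 20, 3, 2.0, seed=5)
        b = synthetic.gen_design_matrix(50, 20, 3, 2.0, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestBundle:
    def test_referential_integrity(self, small_bundle):
        b = small_bundle
        assert set(b.interactions["compound_id"]) <= set(b.compounds["compound_id"])
        assert set(b.interactions["protein_id"]) <= set(b.proteins["protein_id"])
        assert set(b.clouds) == set(b.proteins["protein_id"])

    def test_bundle_write_and_reload(self, small_bundle, tmp_path):
        synthetic.write_bundle(small_bundle, tmp_path)
        assert (tmp_path / "compounds.tsv").exists()
        assert (tmp_path / "signal.json").exists()
        reloaded = pd.read_csv(tmp_path / "interactions.tsv", sep="\t")
        assert len(reloaded) == len(small_bundle.interactions)
        pid = small_bundle.proteins["protein_id"].iloc[0]
        cloud = parse_structure((tmp_path / "pdb" / f"{pid}.pdb").read_text())
        np.testing.assert_allclose(
            cloud.coordinates, small_bundle.clouds[pid], atol=5e-4
        )
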