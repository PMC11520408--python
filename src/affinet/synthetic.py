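"""Synthetic fixture generation: compounds, toy structures, sequences,
subfamily vocabularies and bioactivity tables with a planted sparse signal.

Everything the pipeline consumes can be generated here, bit-reproducibly from
a seed, so the full system is exercisable without any downloads.  The
chemistry is deliberately toy-grade (valid but not drug-like), and the
structures are randomized helices/blobs rather than folds: the fixtures
exist to exercise contracts and signal recovery, not biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .proteins import DEFAULT_SUBFAMILY_VOCABULARY, SUPERFAMILIES
from .sequences import AMINO_ACIDS

# ---- compounds ---------------------------------------------------------------

_CHAIN_ATOMS = ["C", "CC", "CCC", "CO", "CN"]
_RINGS = ["C1CCCCC1", "c1ccccc1", "C1CCNCC1", "c1ccncc1", "C1CCOC1"]
_SUBSTITUENTS = ["O", "N", "Cl", "F", "C(=O)O", "C(=O)N", "OC", "C#N", "S"]


def gen_compounds(n: int, seed: int) -> pd.DataFrame:
    """n distinct, parseable SMILES assembled from a small fragment grammar."""
    if n < 1:
        raise ValueError("need n >= 1 compounds")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("fragment grammar failed to produce enough molecules")
        parts = [str(rng.choice(_CHAIN_ATOMS))]
        if rng.random() < 0.8:
            parts.append(str(rng.choice(_RINGS)))
        for _ in range(rng.integers(0, 4)):
            parts.append(str(rng.choice(_SUBSTITUENTS)))
        if rng.random() < 0.4:
            parts.append(str(rng.choice(_CHAIN_ATOMS)))
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        rows.append({"compound_id": f"CPD{len(rows):05d}", "smiles": canonical})
    return pd.DataFrame(rows)


# ---- structures and sequences ------------------------------------------------


def write_pdb(coordinates: np.ndarray, elements: list[str] | None = None) -> str:
    """Standard-column ATOM records for an atom cloud (one chain, CA trace)."""
    coords = np.asarray(coordinates, dtype=float)
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        el = (elements[i - 1] if elements else "C").rjust(2)
        lines.append(
            f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def random_rotation(seed: int) -> np.ndarray:
    """A proper rotation matrix (orthonormal, determinant +1)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_structure_coords(atoms_per: int, seed: int) -> np.ndarray:
    """Randomized helical backbone with positional jitter (N x 3, Angstrom)."""
    if atoms_per < 5:
        raise ValueError("need at least 5 atoms")
    rng = np.random.default_rng(seed)
    t = np.arange(atoms_per) * 100.0 * np.pi / 180.0  # ~100 deg / residue
    radius = rng.uniform(2.0, 4.0)
    rise = rng.uniform(1.0, 2.0)
    coords = np.stack(
        [radius * np.cos(t), radius * np.sin(t), rise * np.arange(atoms_per)],
        axis=1,
    )
    coords += rng.normal(0, 0.4, size=coords.shape)
    return coords @ random_rotation(int(rng.integers(2**31 - 1))).T


def gen_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteins(
    n_proteins: int,
    atoms_per: int,
    seed: int,
    superfamily: str = "kinase",
    vocabulary: tuple[str, ...] = DEFAULT_SUBFAMILY_VOCABULARY,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Protein table (sequence, superfamily, subfamily) plus atom clouds."""
    if superfamily not in SUPERFAMILIES:
        raise ValueError(f"unknown superfamily {superfamily!r}")
    rng = np.random.default_rng(seed)
    rows, clouds = [], {}
    for i in range(n_proteins):
        pid = f"PROT{i:04d}"
        clouds[pid] = gen_structure_coords(
            atoms_per, int(rng.integers(2**31 - 1))
        )
        rows.append(
            {
                "protein_id": pid,
                "sequence": gen_sequence(int(rng.integers(40, 80)), rng),
                "superfamily": superfamily,
                "subfamily": str(rng.choice(vocabulary)),
            }
        )
    return pd.DataFrame(rows), clouds


# ---- interaction tables with a planted signal --------------------------------


@dataclass
class SignalSpec:
    """Ground truth linking descriptor columns to the generated labels."""

    informative_indices: np.ndarray
    weights: np.ndarray
    noise_sd: float = 0.1
    pchembl_range: tuple[float, float] = (2.0, 11.0)
    seed: int = 0

    def __post_init__(self):
        self.informative_indices = np.asarray(self.informative_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.informative_indices) != len(self.weights):
            raise ValueError("indices and weights must align")


def gen_interactions(
    pair_features: np.ndarray,
    pairs: pd.DataFrame,
    spec: SignalSpec,
    duplicate_rate: float = 0.0,
    conflict_rate: float = 0.0,
) -> pd.DataFrame:
    """Bioactivity table whose labels follow a sparse linear latent signal.

    ``pair_features`` holds one descriptor row per row of ``pairs``
    (compound_id, protein_id[, superfamily]).  The pChEMBL-like label is an
    affine map of the standardized latent plus Gaussian noise, clipped to the
    declared range; the interaction score is a logistic squashing of the same
    latent, so the two label types agree in ranking.  Duplicates (jittered
    labels) and active/inactive conflicts are injected at the given rates.
    """
    if not (0 <= duplicate_rate < 1 and 0 <= conflict_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    X = np.asarray(pair_features, dtype=float)
    if spec.informative_indices.max(initial=-1) >= X.shape[1]:
        raise ValueError("informative index out of descriptor bounds")
    latent = X[:, spec.informative_indices] @ spec.weights
    sd = latent.std()
    z = (latent - latent.mean()) / (sd if sd > 0 else 1.0)
    lo, hi = spec.pchembl_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    pchembl = np.clip(
        mid + 0.45 * half * z + rng.normal(0, spec.noise_sd, len(z)), lo, hi
    )
    score = 1.0 / (1.0 + np.exp(-1.5 * z))

    df = pairs.reset_index(drop=True).copy()
    df["pchembl"] = pchembl
    df["dtp_score"] = score
    df["source_doc"] = [f"DOC{i % 17:03d}" for i in range(len(df))]
    df["activity_flag"] = np.where(pchembl > 5.0, "active", "inactive")

    extra = []
    n_dup = int(round(duplicate_rate * len(df)))
    for i in rng.choice(len(df), size=n_dup, replace=False) if n_dup else []:
        row = df.iloc[int(i)].copy()
        row["pchembl"] = float(
            np.clip(row["pchembl"] + rng.normal(0, 0.3), lo, hi)
        )
        row["dtp_score"] = float(np.clip(row["dtp_score"] + rng.normal(0, 0.05), 0, 1))
        extra.append(row)
    n_conf = int(round(conflict_rate * len(df)))
    for i in rng.choice(len(df), size=n_conf, replace=False) if n_conf else []:
        row = df.iloc[int(i)].copy()
        row["activity_flag"] = (
            "inactive" if row["activity_flag"] == "active" else "active"
        )
        extra.append(row)
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(
        drop=True
    )


def gen_design_matrix(
    n: int, p: int, k_informative: int, snr: float, seed: int
) -> tuple[np.ndarray, np.ndarray, SignalSpec]:
    """Gaussian design with a planted k-sparse linear signal at a given SNR.

    Returns (X, y, spec); the noise variance is set so that
    Var(signal) / Var(noise) = snr.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    idx = rng.choice(p, size=k_informative, replace=False)
    w = rng.uniform(0.5, 1.5, size=k_informative) * rng.choice([-1, 1], k_informative)
    signal = X[:, idx] @ w
    noise_sd = signal.std() / np.sqrt(snr)
    y = signal + rng.normal(0, noise_sd, size=n)
    spec = SignalSpec(
        informative_indices=np.sort(idx),
        weights=w[np.argsort(idx)],
        noise_sd=float(noise_sd),
        seed=seed,
    )
    return X, y, spec


# ---- full bundle -------------------------------------------------------------


@dataclass
class FixtureBundle:
    compounds: pd.DataFrame
    proteins: pd.DataFrame
    clouds: dict[str, np.ndarray]
    interactions: pd.DataFrame
    signal: SignalSpec
    compound_phases: dict[str, str] = field(default_factory=dict)


def make_bundle(
    n_compounds: int = 30,
    n_proteins: int = 6,
    n_pairs: int = 150,
    seed: int = 0,
    duplicate_rate: float = 0.05,
    conflict_rate: float = 0.02,
    noise_sd: float = 0.1,
    superfamily: str = "kinase",
    atoms_per: int = 40,
    featurize_kwargs: dict | None = None,
) -> FixtureBundle:
    """Generate a referentially consistent bundle of all pipeline inputs.

    The planted signal lives in the pair descriptor space produced by the
    package's own featurizers (compound physchem/fingerprints, protein
    Zernike/sequence blocks), so downstream selection and model fitting can
    demonstrably recover it.
    """
    from .pairs import build_pair_features  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    compounds = gen_compounds(n_compounds, int(rng.integers(2**31 - 1)))
    proteins, clouds = gen_proteins(
        n_proteins, atoms_per, int(rng.integers(2**31 - 1)), superfamily
    )
    n_pairs = min(n_pairs, n_compounds * n_proteins)
    all_pairs = [
        (c, p) for c in compounds["compound_id"] for p in proteins["protein_id"]
    ]
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    pairs = pd.DataFrame(
        [all_pairs[i] for i in chosen], columns=["compound_id", "protein_id"]
    )
    pairs["superfamily"] = superfamily

    feats = build_pair_features(
        pairs, compounds, proteins, clouds, **(featurize_kwargs or {"grid_size": 16, "n_max": 6})
    )
    X = feats.concatenated()
    pool = np.setdiff1d(np.arange(X.shape[1]), feats.layout.subfamily_indices)
    varying = pool[X[:, pool].std(axis=0) > 1e-9]
    k = min(12, len(varying))
    idx = rng.choice(varying, size=k, replace=False)
    Xs = (X[:, idx] - X[:, idx].mean(0)) / X[:, idx].std(0)
    w = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1, 1], k)
    spec = SignalSpec(
        informative_indices=np.sort(idx),
        weights=w[np.argsort(idx)],
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    # the latent acts on standardized informative columns so no single
    # unit-heavy descriptor dominates
    full = np.zeros((len(pairs), X.shape[1]))
    full[:, idx] = Xs
    interactions = gen_interactions(
        full, pairs, spec, duplicate_rate=duplicate_rate, conflict_rate=conflict_rate
    )
    rng_ph = np.random.default_rng(seed + 7)
    phases = {
        cid: str(rng_ph.choice(["approved", "phase3", "phase2", "preclinical"]))
        for cid in compounds["compound_id"]
    }
    return FixtureBundle(
        compounds=compounds,
        proteins=proteins,
        clouds=clouds,
        interactions=interactions,
        signal=spec,
        compound_phases=phases,
    )


def write_bundle(bundle: FixtureBundle, out_dir: Path):
    """Write the bundle as TSV tables, a PDB directory, FASTA and JSON truth."""
    out = Path(out_dir)
    (out / "pdb").mkdir(parents=True, exist_ok=True)
    bundle.compounds.to_csv(out / "compounds.tsv", sep="\t", index=False)
    bundle.proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
    bundle.interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
    for pid, coords in bundle.clouds.items():
        (out / "pdb" / f"{pid}.pdb").write_text(write_pdb(coords))
    with open(out / "sequences.fasta", "w") as f:
        for _, row in bundle.proteins.iterrows():
            f.write(f">{row['protein_id']}\n{row['sequence']}\n")
    truth = {
        "informative_indices": bundle.signal.informative_indices.tolist(),
        "weights": bundle.signal.weights.tolist(),
        "noise_sd": bundle.signal.noise_sd,
        "compound_phases": bundle.compound_phases,
    }
    (out / "signal.json").write_text(json.dumps(truth, indent=1))
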