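"""Sequence-composition descriptors for proteins: a fixed 576-long block.

Layout (order is frozen; offsets recorded in ``SEQUENCE_BLOCK_BOUNDS``):

- 20 mono-residue frequencies (alphabetical one-letter codes), summing to 1;
- 400 di-residue frequencies (row-major over the same order), summing to 1;
- 3 property scales (hydrophobicity, polarizability, aromaticity), each
  contributing 50 lag-autocorrelations (lags 1..50 of the per-sequence
  standardized property profile, zero when lag >= length) plus the raw
  profile mean and variance: 3 x 52 = 156.

Total 20 + 400 + 156 = 576.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

N_LAGS = 50
SEQUENCE_DIM = 20 + 400 + 3 * (N_LAGS + 2)  # 576

SEQUENCE_BLOCK_BOUNDS = {
    "mono_freq": (0, 20),
    "di_freq": (20, 420),
    "hydrophobicity": (420, 472),
    "polarizability": (472, 524),
    "aromaticity": (524, 576),
}

# Kyte-Doolittle hydropathy
HYDROPHOBICITY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
# side-chain polarizability (A^3), Charton & Charton-style scale
POLARIZABILITY = {
    "A": 0.046, "C": 0.128, "D": 0.105, "E": 0.151, "F": 0.290, "G": 0.000,
    "H": 0.230, "I": 0.186, "K": 0.219, "L": 0.186, "M": 0.221, "N": 0.134,
    "P": 0.131, "Q": 0.180, "R": 0.291, "S": 0.062, "T": 0.108, "V": 0.140,
    "W": 0.409, "Y": 0.298,
}
# indicator of an aromatic side chain
AROMATICITY = {a: (1.0 if a in "FWY" else 0.0) for a in AMINO_ACIDS}

PROPERTY_SCALES = (
    ("hydrophobicity", HYDROPHOBICITY),
    ("polarizability", POLARIZABILITY),
    ("aromaticity", AROMATICITY),
)


class NonstandardResidueError(ValueError):
    def __init__(self, residue: str, position: int):
        super().__init__(
            f"nonstandard residue {residue!r} at position {position}; "
            f"expected one of {AMINO_ACIDS}"
        )


def _clean(sequence: str, strict: bool) -> str:
    seq = sequence.upper()
    kept = []
    for i, ch in enumerate(seq):
        if ch in _AA_INDEX:
            kept.append(ch)
        elif strict:
            raise NonstandardResidueError(ch, i)
    return "".join(kept)


def _autocorrelations(profile: np.ndarray) -> np.ndarray:
    """Lag-1..N_LAGS mean products of the standardized profile."""
    L = len(profile)
    sd = profile.std()
    z = (profile - profile.mean()) / sd if sd > 0 else np.zeros(L)
    ac = np.zeros(N_LAGS)
    for lag in range(1, N_LAGS + 1):
        if lag < L:
            ac[lag - 1] = np.mean(z[:-lag] * z[lag:])
    return ac


def sequence_descriptors(sequence: str, strict: bool = True) -> np.ndarray:
    """Compute the 576-long composition/property block for one sequence.

    In strict mode (default) a residue outside the 20-letter alphabet raises;
    in lenient mode it is skipped.
    """
    seq = _clean(sequence, strict)
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 standard residues")
    idx = np.array([_AA_INDEX[a] for a in seq])
    L = len(idx)

    mono = np.bincount(idx, minlength=20) / L
    di = np.zeros((20, 20))
    np.add.at(di, (idx[:-1], idx[1:]), 1.0)
    di /= L - 1

    blocks = [mono, di.ravel()]
    for _, scale in PROPERTY_SCALES:
        profile = np.array([scale[a] for a in seq])
        blocks.append(
            np.concatenate(
                [_autocorrelations(profile), [profile.mean(), profile.var()]]
            )
        )
    out = np.concatenate(blocks)
    assert out.shape == (SEQUENCE_DIM,)
    return out


def sequence_labels() -> list[str]:
    labels = [f"seq_mono_{a}" for a in AMINO_ACIDS]
    labels += [f"seq_di_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    for name, _ in PROPERTY_SCALES:
        labels += [f"seq_{name}_lag{k}" for k in range(1, N_LAGS + 1)]
        labels += [f"seq_{name}_mean", f"seq_{name}_var"]
    return labels
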