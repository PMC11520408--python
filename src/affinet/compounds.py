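"""Compound featurization: binary fingerprints and physicochemical descriptors.

Each compound is represented by five concatenated fingerprint blocks
(MACCS 166, path-hashed 2048, Avalon 512, circular radius-2 2048,
feature-circular radius-2 2048; 6822 bits in total) plus a 200-long vector of
continuous physicochemical descriptors.  Tanimoto similarity utilities
operate on the bit blocks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator as _rfg

from .physchem_names import PHYSCHEM_NAMES

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: (name, length) of each fingerprint sub-block, in concatenation order.
FINGERPRINT_BLOCKS = (
    ("maccs", 166),
    ("path_hashed", 2048),
    ("avalon", 512),
    ("circular_r2", 2048),
    ("feature_circular_r2", 2048),
)

FINGERPRINT_TOTAL = sum(length for _, length in FINGERPRINT_BLOCKS)  # 6822
PHYSCHEM_DIM = len(PHYSCHEM_NAMES)  # 200


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str


@dataclass(frozen=True)
class FingerprintBlock:
    """The five binary fingerprint sub-blocks of one compound."""

    maccs: np.ndarray
    path_hashed: np.ndarray
    avalon: np.ndarray
    circular_r2: np.ndarray
    feature_circular_r2: np.ndarray

    def __post_init__(self):
        for name, length in FINGERPRINT_BLOCKS:
            block = getattr(self, name)
            if block.shape != (length,):
                raise ValueError(f"{name} block must have length {length}")

    def concatenated(self) -> np.ndarray:
        return np.concatenate(
            [getattr(self, name) for name, _ in FINGERPRINT_BLOCKS]
        )


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def _bits(fp, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


_path_gen = _rfg.GetRDKitFPGenerator(fpSize=2048)
_morgan_gen = _rfg.GetMorganGenerator(radius=2, fpSize=2048)
_featmorgan_gen = _rfg.GetMorganGenerator(
    radius=2, fpSize=2048, atomInvariantsGenerator=_rfg.GetMorganFeatureAtomInvGen()
)


def compute_fingerprints(record: CompoundRecord) -> FingerprintBlock:
    """Compute the five fingerprint sub-blocks for one compound.

    The toolkit's MACCS implementation emits 167 bits with bit 0 as an unused
    placeholder; it is stripped so the block is exactly 166 bits.
    """
    mol = _mol_from_smiles(record.smiles)
    maccs167 = _bits(MACCSkeys.GenMACCSKeys(mol), 167)
    return FingerprintBlock(
        maccs=maccs167[1:].copy(),
        path_hashed=_bits(_path_gen.GetFingerprint(mol), 2048),
        avalon=_bits(pyAvalonTools.GetAvalonFP(mol, nBits=512), 512),
        circular_r2=_bits(_morgan_gen.GetFingerprint(mol), 2048),
        feature_circular_r2=_bits(_featmorgan_gen.GetFingerprint(mol), 2048),
    )


_DESC_FNS = dict(Descriptors._descList)


def compute_physchem(record: CompoundRecord) -> np.ndarray:
    """200-long physicochemical vector in the frozen ``PHYSCHEM_NAMES`` order.

    A descriptor that raises or returns a non-finite value for a molecule is
    recorded as 0.0 with a logged warning, so the vector stays finite.
    """
    mol = _mol_from_smiles(record.smiles)
    missing = [n for n in PHYSCHEM_NAMES if n not in _DESC_FNS]
    if missing:
        raise RuntimeError(
            f"toolkit does not provide frozen descriptors: {missing}"
        )
    values = np.zeros(PHYSCHEM_DIM, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(PHYSCHEM_NAMES):
            try:
                v = float(_DESC_FNS[name](mol))
            except Exception:
                logger.warning(
                    "descriptor %s failed for %s; recorded as 0",
                    name,
                    record.compound_id,
                )
                v = 0.0
            if not np.isfinite(v):
                logger.warning(
                    "descriptor %s non-finite for %s; recorded as 0",
                    name,
                    record.compound_id,
                )
                v = 0.0
            values[i] = v
    return values


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient c / (a + b - c) between two bit vectors.

    Defined as 0 (with a warning) when both vectors are all-zero, where the
    formula itself is 0/0.
    """
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprints must have equal length")
    a = int(fp_a.sum())
    b = int(fp_b.sum())
    c = int((fp_a & fp_b).sum())
    if a + b == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; defined as 0")
        return 0.0
    return c / (a + b - c)


def mean_cross_tanimoto(set_a: list[np.ndarray], set_b: list[np.ndarray]) -> float:
    """Mean Tanimoto over the full |A| x |B| cross product of two sets.

    Used to quantify compound-set similarity between training and validation
    sets; the convention is to compute it on the path-hashed block.
    """
    if not set_a or not set_b:
        raise ValueError("both fingerprint sets must be nonempty")
    A = np.asarray(np.stack(set_a), dtype=bool)
    B = np.asarray(np.stack(set_b), dtype=bool)
    a = A.sum(axis=1)[:, None].astype(np.int64)
    b = B.sum(axis=1)[None, :].astype(np.int64)
    c = (A.astype(np.int64) @ B.T.astype(np.int64))
    denom = a + b - c
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, c / np.where(denom == 0, 1, denom), 0.0)
    return float(sim.mean())


def featurize_compounds(records: list[CompoundRecord]):
    """Descriptor matrix for a compound table.

    Returns ``(ids, continuous, binary, block_boundaries)`` where continuous is
    n x 200 physchem values, binary is n x 6822 fingerprint bits, and
    block_boundaries maps each sub-block name to its (start, stop) offsets
    within the concatenation [continuous | binary].
    """
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("compound_id values must be unique")
    continuous = np.stack([compute_physchem(r) for r in records])
    binary = np.stack(
        [compute_fingerprints(r).concatenated() for r in records]
    ).astype(np.uint8)
    boundaries = {"physchem": (0, PHYSCHEM_DIM)}
    offset = PHYSCHEM_DIM
    for name, length in FINGERPRINT_BLOCKS:
        boundaries[name] = (offset, offset + length)
        offset += length
    return ids, continuous, binary, boundaries
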