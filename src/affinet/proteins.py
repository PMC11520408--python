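"""Protein featurization: structure parsing, Zernike + sequence descriptors,
and binary subfamily labels.

The protein side of a pair representation is a 121-long Zernike surface block
and a 576-long sequence-composition block (both continuous) plus a one-hot
subfamily label block (binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import zernike
from .sequences import SEQUENCE_DIM, sequence_descriptors, sequence_labels

SUPERFAMILIES = (
    "enzyme",
    "kinase",
    "GPCR",
    "nuclear receptor",
    "epigenetic regulator",
    "ion channel",
    "transporter",
)

#: Reference subfamily vocabulary (11 labels). With 121 Zernike + 576 sequence
#: + 200 physicochemical + 6822 fingerprint bits = 7719 selectable descriptors,
#: the 11 always-kept subfamily labels bring the full vector to 7730.
DEFAULT_SUBFAMILY_VOCABULARY = (
    "tyrosine_kinase",
    "serine_threonine_kinase",
    "amine_receptor",
    "chemokine_receptor",
    "peptide_receptor",
    "protease",
    "oxidoreductase",
    "steroid_receptor",
    "bromodomain",
    "voltage_gated",
    "slc_transporter",
)

_WATER_RESIDUES = {"HOH", "WAT", "DOD"}


class StructureParseError(ValueError):
    pass


class EmptyStructureError(StructureParseError):
    pass


@dataclass
class AtomCloud:
    protein_id: str
    coordinates: np.ndarray  # N x 3, Angstrom
    elements: list[str]

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N x 3")
        if len(self.coordinates) < 1:
            raise EmptyStructureError("atom cloud must contain >= 1 atom")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")


def parse_structure(pdb_text: str, protein_id: str = "") -> AtomCloud:
    """Read ATOM records of the first model from fixed-column PDB text.

    HETATM records and waters are skipped; parsing stops at the first ENDMDL
    so multi-model files contribute only their first model.
    """
    coords = []
    elements = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("ENDMDL"):
            break
        if not line.startswith("ATOM"):
            continue
        resname = line[17:20].strip()
        if resname in _WATER_RESIDUES:
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise StructureParseError(
                f"malformed coordinate columns on line {lineno}: {line!r}"
            ) from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = line[12:16].strip()[:1]
        coords.append((x, y, z))
        elements.append(element)
    if not coords:
        raise EmptyStructureError("no ATOM records found")
    return AtomCloud(
        protein_id=protein_id, coordinates=np.array(coords), elements=elements
    )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    superfamily: str
    subfamily: str
    structure: AtomCloud | None = None

    def __post_init__(self):
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(
                f"unknown superfamily {self.superfamily!r}; "
                f"expected one of {SUPERFAMILIES}"
            )


def subfamily_onehot(
    subfamily: str, vocabulary: tuple[str, ...] = DEFAULT_SUBFAMILY_VOCABULARY
) -> np.ndarray:
    """One-hot encode a subfamily label over a fixed vocabulary."""
    if subfamily not in vocabulary:
        raise ValueError(
            f"unknown subfamily {subfamily!r}; vocabulary: {list(vocabulary)}"
        )
    vec = np.zeros(len(vocabulary), dtype=np.uint8)
    vec[vocabulary.index(subfamily)] = 1
    return vec


def featurize_proteins(
    records: list[ProteinRecord],
    vocabulary: tuple[str, ...] = DEFAULT_SUBFAMILY_VOCABULARY,
    grid_size: int = zernike.DEFAULT_GRID,
    gaussian_width: float = zernike.DEFAULT_GAUSSIAN_WIDTH,
    scale_radius: float = zernike.DEFAULT_SCALE_RADIUS,
    n_max: int = zernike.DEFAULT_N_MAX,
):
    """Descriptor matrices for a protein table.

    Returns ``(ids, continuous, binary, block_boundaries)``: continuous is
    n x (121 + 576) [Zernike | sequence], binary is the n x |vocabulary|
    one-hot subfamily block.  Offsets in block_boundaries are relative to the
    concatenation [continuous | binary].
    """
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("protein_id values must be unique")
    zern_dim = len(zernike.valid_nl(n_max))
    continuous = np.zeros((len(records), zern_dim + SEQUENCE_DIM))
    binary = np.zeros((len(records), len(vocabulary)), dtype=np.uint8)
    for i, rec in enumerate(records):
        if rec.structure is None:
            raise ValueError(f"protein {rec.protein_id} has no structure")
        continuous[i, :zern_dim] = zernike.compute_descriptors(
            rec.structure.coordinates,
            grid_size=grid_size,
            gaussian_width=gaussian_width,
            scale_radius=scale_radius,
            n_max=n_max,
        )
        continuous[i, zern_dim:] = sequence_descriptors(rec.sequence)
        binary[i] = subfamily_onehot(rec.subfamily, vocabulary)
    boundaries = {
        "zernike": (0, zern_dim),
        "sequence": (zern_dim, zern_dim + SEQUENCE_DIM),
        "subfamily": (zern_dim + SEQUENCE_DIM, zern_dim + SEQUENCE_DIM + len(vocabulary)),
    }
    return ids, continuous, binary, boundaries


def protein_feature_labels(
    vocabulary: tuple[str, ...] = DEFAULT_SUBFAMILY_VOCABULARY,
    n_max: int = zernike.DEFAULT_N_MAX,
) -> list[str]:
    return (
        zernike.invariant_labels(n_max)
        + sequence_labels()
        + [f"subfamily_{s}" for s in vocabulary]
    )
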