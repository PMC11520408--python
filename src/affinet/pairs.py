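"""Assembly of per-pair descriptor matrices from compound and protein tables.

A pair's representation concatenates four blocks in fixed order:

    [compound continuous | compound binary | protein continuous | protein binary]

i.e. physicochemical descriptors, fingerprint bits, Zernike + sequence
descriptors, and one-hot subfamily labels.  ``PairLayout`` records the block
offsets so a global descriptor index (e.g. from a selection mask) can be
routed back to its block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import CompoundRecord, featurize_compounds
from .proteins import DEFAULT_SUBFAMILY_VOCABULARY, ProteinRecord, featurize_proteins
from . import zernike


@dataclass
class PairLayout:
    """Column offsets of the four blocks in the concatenated pair vector."""

    n_cc: int  # compound continuous
    n_cb: int  # compound binary
    n_pc: int  # protein continuous
    n_pb: int  # protein binary (subfamily labels)

    @property
    def total(self) -> int:
        return self.n_cc + self.n_cb + self.n_pc + self.n_pb

    @property
    def offsets(self) -> dict[str, tuple[int, int]]:
        o1 = self.n_cc
        o2 = o1 + self.n_cb
        o3 = o2 + self.n_pc
        return {
            "compound_continuous": (0, o1),
            "compound_binary": (o1, o2),
            "protein_continuous": (o2, o3),
            "protein_binary": (o3, self.total),
        }

    @property
    def subfamily_indices(self) -> np.ndarray:
        lo, hi = self.offsets["protein_binary"]
        return np.arange(lo, hi)

    def split_mask(self, global_indices: np.ndarray) -> dict[str, np.ndarray]:
        """Route global column indices into block-local index arrays."""
        out = {}
        for name, (lo, hi) in self.offsets.items():
            sel = global_indices[(global_indices >= lo) & (global_indices < hi)]
            out[name] = np.sort(sel) - lo
        return out


@dataclass
class PairFeatures:
    """Per-pair feature blocks aligned with an interaction table."""

    compound_continuous: np.ndarray
    compound_binary: np.ndarray
    protein_continuous: np.ndarray
    protein_binary: np.ndarray
    layout: PairLayout

    def concatenated(self) -> np.ndarray:
        return np.concatenate(
            [
                self.compound_continuous,
                self.compound_binary,
                self.protein_continuous,
                self.protein_binary,
            ],
            axis=1,
        )

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.compound_continuous,
            self.compound_binary,
            self.protein_continuous,
            self.protein_binary,
        )


def build_pair_features(
    pairs: pd.DataFrame,
    compounds: pd.DataFrame,
    proteins: pd.DataFrame,
    clouds: dict[str, np.ndarray],
    vocabulary: tuple[str, ...] = DEFAULT_SUBFAMILY_VOCABULARY,
    grid_size: int = zernike.DEFAULT_GRID,
    gaussian_width: float = zernike.DEFAULT_GAUSSIAN_WIDTH,
    scale_radius: float = zernike.DEFAULT_SCALE_RADIUS,
    n_max: int = zernike.DEFAULT_N_MAX,
) -> PairFeatures:
    """Featurize each unique compound/protein once and gather per-pair rows."""
    from .proteins import AtomCloud

    comp_records = [
        CompoundRecord(row.compound_id, row.smiles)
        for row in compounds.itertuples()
    ]
    cids, c_cont, c_bin, _ = featurize_compounds(comp_records)

    prot_records = [
        ProteinRecord(
            protein_id=row.protein_id,
            sequence=row.sequence,
            superfamily=row.superfamily,
            subfamily=row.subfamily,
            structure=AtomCloud(
                protein_id=row.protein_id,
                coordinates=clouds[row.protein_id],
                elements=["C"] * len(clouds[row.protein_id]),
            ),
        )
        for row in proteins.itertuples()
    ]
    pids, p_cont, p_bin, _ = featurize_proteins(
        prot_records,
        vocabulary=vocabulary,
        grid_size=grid_size,
        gaussian_width=gaussian_width,
        scale_radius=scale_radius,
        n_max=n_max,
    )

    c_index = {cid: i for i, cid in enumerate(cids)}
    p_index = {pid: i for i, pid in enumerate(pids)}
    ci = np.array([c_index[c] for c in pairs["compound_id"]])
    pi = np.array([p_index[p] for p in pairs["protein_id"]])

    layout = PairLayout(
        n_cc=c_cont.shape[1],
        n_cb=c_bin.shape[1],
        n_pc=p_cont.shape[1],
        n_pb=p_bin.shape[1],
    )
    return PairFeatures(
        compound_continuous=c_cont[ci],
        compound_binary=c_bin[ci].astype(np.float64),
        protein_continuous=p_cont[pi],
        protein_binary=p_bin[pi].astype(np.float64),
        layout=layout,
    )
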