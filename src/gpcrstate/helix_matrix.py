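"""7x7 per-helix RMSD matrices between an inactive/active structure pair.

Entry (r, j) is the C-alpha RMSD of helix j after superposing the second
structure onto the first using helix r's C-alpha atoms — no re-fit per
column. Aligning on each helix in turn separates which helices move
relative to which: a receptor whose activation remodels most helix pairs
shows large values across the whole matrix, while a single rigid-helix
movement confines them to one row and column.

Helix pairing is by residue number within the segment ranges; residues
resolved in only one structure are trimmed symmetrically (a warning is
emitted), since deposited models differ in their modelled termini.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PairingError
from .geometry import pair_ca_atoms, superpose
from .structure_model import Structure, TMSegmentTable

__all__ = ["RMSDMatrix", "rmsd_matrix_7x7", "movement_profile", "matrix_to_tsv"]


@dataclass
class RMSDMatrix:
    """values[r][j]: RMSD of helix j when aligned on helix r; labels TM1..TM7."""

    values: np.ndarray  # (7, 7), A
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (7, 7):
            raise ValueError("matrix must be 7x7")
        if np.any(self.values < 0):
            raise ValueError("RMSD entries must be nonnegative")


def rmsd_matrix_7x7(a: Structure, b: Structure, segs: TMSegmentTable) -> RMSDMatrix:
    """Per-helix RMSD matrix between two structures sharing numbering."""
    names = segs.names()
    paired: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in names:
        chain, lo, hi = segs[name]
        try:
            pa, pb = pair_ca_atoms(a, b, [(chain, lo, hi)], strict=False)
        except PairingError as e:
            raise PairingError(f"helix {name}: {e}") from e
        if len(pa) < 4:
            raise PairingError(f"helix {name}: fewer than 4 paired C-alpha atoms")
        n_range = hi - lo + 1
        if len(pa) < n_range:
            warnings.warn(
                f"helix {name}: {n_range - len(pa)} unpaired residues trimmed",
                stacklevel=2,
            )
        paired[name] = (pa, pb)

    values = np.empty((7, 7))
    for r, align_name in enumerate(names):
        pa, pb = paired[align_name]
        transform, _ = superpose(pb, pa)  # b onto a using helix r
        for j, meas_name in enumerate(names):
            qa, qb = paired[meas_name]
            moved = transform.apply(qb)
            values[r, j] = float(np.sqrt(np.mean(np.sum((moved - qa) ** 2, axis=1))))
    return RMSDMatrix(values=values, labels=names)


def movement_profile(
    m: RMSDMatrix, threshold: float
) -> tuple[int, list[tuple[str, str]]]:
    """Off-diagonal entries above threshold: count and (align, measured) pairs."""
    pairs = [
        (m.labels[r], m.labels[j])
        for r in range(7)
        for j in range(7)
        if r != j and m.values[r, j] > threshold
    ]
    return len(pairs), pairs


def matrix_to_tsv(m: RMSDMatrix, path) -> None:
    pd.DataFrame(np.round(m.values, 2), index=list(m.labels), columns=list(m.labels)).to_csv(
        path, sep="\t", index_label="aligned_on"
    )
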