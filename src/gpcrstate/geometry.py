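"""Numeric kernel: Kabsch superposition, RMSD, distances, centroids, dihedrals.

All angles are degrees in (-180, 180]. The dihedral sign convention is IUPAC
(positive = clockwise rotation of the far bond relative to the near bond when
viewed from the second atom toward the third); it is applied consistently to
backbone and side-chain (chi) angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    GeometryError,
    IncompleteSideChainError,
    NoChiAngleError,
    PairingError,
)
from .structure_model import Residue, Structure

__all__ = [
    "RigidTransform",
    "superpose",
    "rmsd_after_superposition",
    "atom_distance",
    "ring_centroid",
    "dihedral",
    "chi_angles",
    "wrap_angle",
    "angle_difference",
    "pair_ca_atoms",
    "BENZENE_RING_ATOMS",
]

#: Atom names of the six-membered benzene ring of Phe/Tyr.
BENZENE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


@dataclass
class RigidTransform:
    """Proper rotation plus translation; maps x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    w = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def angle_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles on the circle, deg."""
    return abs(wrap_angle(a - b))


def _as_points(x: np.ndarray, min_points: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) point set, got shape {x.shape}")
    if x.shape[0] < min_points:
        raise GeometryError(f"need >= {min_points} points, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise GeometryError("non-finite coordinates in point set")
    return x


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns the minimizing proper-rotation transform and the minimized RMSD.
    The determinant correction flips the smallest singular vector so the
    result is always a rotation, never a reflection.
    """
    mobile = _as_points(mobile, 3)
    reference = _as_points(reference, 3)
    if mobile.shape != reference.shape:
        raise GeometryError(
            f"point counts differ: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    # Degeneracy check: collinear (or coincident) sets leave the rotation
    # underdetermined about the common axis.
    for pts in (x, y):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise GeometryError("degenerate (collinear) point set")
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    transform = RigidTransform(rotation=rot, translation=t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def atom_distance(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise GeometryError("non-finite input to atom_distance")
    return float(np.linalg.norm(p - q))


def ring_centroid(res: Residue, ring_atoms: tuple[str, ...] = BENZENE_RING_ATOMS) -> np.ndarray:
    """Arithmetic mean of the named ring atoms' positions."""
    points = []
    for name in ring_atoms:
        if not res.has_atom(name):
            raise IncompleteSideChainError(
                f"residue {res.res_name} {res.key()} is missing ring atom {name!r}"
            )
        points.append(res.atom(name).position)
    return np.mean(points, axis=0)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention.

    0 deg for cis (p1 and p4 eclipsed), 180 deg for trans.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1)
    if np.linalg.norm(b0) < 1e-9 or n1 < 1e-9 or np.linalg.norm(b2) < 1e-9:
        raise GeometryError("coincident consecutive points in dihedral")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise GeometryError("degenerate (collinear) dihedral geometry")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


# chi1 is N-CA-CB-G where G is the first side-chain gamma atom; chi2 is
# CA-CB-G-D. Only residue types used by the pipeline are tabulated; Trp chi2
# is defined on CD1, matching the convention used for the toggle switch.
_CHI1_GAMMA = {
    "PHE": "CG", "TYR": "CG", "TRP": "CG", "HIS": "CG", "LEU": "CG",
    "MET": "CG", "GLU": "CG", "GLN": "CG", "LYS": "CG", "ARG": "CG",
    "ASP": "CG", "ASN": "CG", "PRO": "CG",
    "SER": "OG", "CYS": "SG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1",
}
_CHI2_DELTA = {
    "PHE": "CD1", "TYR": "CD1", "TRP": "CD1", "HIS": "CD1", "LEU": "CD1",
    "MET": "SD", "GLU": "CD", "GLN": "CD", "LYS": "CD", "ARG": "CD",
    "ILE": "CD1",
}


def chi_angles(res: Residue) -> tuple[float, float | None]:
    """(chi1, chi2) side-chain dihedrals in degrees; chi2 None if undefined.

    Raises :class:`NoChiAngleError` for Ala/Gly — the signal used to detect
    alanine-substituted toggle positions, where the classifier does not apply.
    """
    rn = res.res_name.upper()
    if rn in ("ALA", "GLY") or rn not in _CHI1_GAMMA:
        raise NoChiAngleError(f"residue type {res.res_name!r} has no chi angles")
    gamma = _CHI1_GAMMA[rn]
    for name in ("N", "CA", "CB", gamma):
        if not res.has_atom(name):
            raise IncompleteSideChainError(
                f"residue {res.res_name} {res.key()} is missing atom {name!r}"
            )
    chi1 = dihedral(
        res.atom("N").position,
        res.atom("CA").position,
        res.atom("CB").position,
        res.atom(gamma).position,
    )
    chi2: float | None = None
    delta = _CHI2_DELTA.get(rn)
    if delta is not None:
        if not res.has_atom(delta):
            raise IncompleteSideChainError(
                f"residue {res.res_name} {res.key()} is missing atom {delta!r}"
            )
        chi2 = dihedral(
            res.atom("CA").position,
            res.atom("CB").position,
            res.atom(gamma).position,
            res.atom(delta).position,
        )
    return chi1, chi2


def pair_ca_atoms(
    a: Structure,
    b: Structure,
    ranges: list[tuple[str, int, int]],
    atom_name: str = "CA",
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired atom coordinates over residue ranges shared by two structures.

    With ``strict=True`` a residue (with the named atom) present in one
    structure but not the other raises a :class:`PairingError` listing the
    missing residues; otherwise unpaired residues are trimmed symmetrically.
    """
    pa, pb, missing = [], [], []
    n_candidates = 0
    for chain, lo, hi in ranges:
        for seq in range(lo, hi + 1):
            in_a = a.has_residue(chain, seq) and a.get_residue(chain, seq).has_atom(atom_name)
            in_b = b.has_residue(chain, seq) and b.get_residue(chain, seq).has_atom(atom_name)
            if in_a or in_b:
                n_candidates += 1
            if in_a and in_b:
                pa.append(a.get_residue(chain, seq).atom(atom_name).position)
                pb.append(b.get_residue(chain, seq).atom(atom_name).position)
            elif in_a != in_b:
                missing.append((chain, seq, "b" if in_a else "a"))
    if strict and missing:
        raise PairingError(
            "unpaired residues in selection: "
            + ", ".join(f"{c}{s} (absent from {side})" for c, s, side in missing)
        )
    if n_candidates == 0 or not pa:
        raise PairingError("selection resolves to no paired atoms")
    return np.array(pa), np.array(pb)


def rmsd_after_superposition(
    a: Structure,
    b: Structure,
    ranges: list[tuple[str, int, int]],
    atom_name: str = "CA",
) -> float:
    """Minimized RMSD of the named atoms over residue ranges, after Kabsch."""
    pa, pb = pair_ca_atoms(a, b, ranges, atom_name=atom_name, strict=True)
    _, rmsd = superpose(pb, pa)
    return rmsd
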