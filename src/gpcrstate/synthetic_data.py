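"""Synthetic seven-helix receptor bundles and frame series with known truth.

The generator emulates the geometry that distinguishes active from inactive
class A receptor structures, on a CB1-like residue numbering:

* seven ideal alpha-helices (rise ~1.5 A/residue, ~100 deg/residue) on a
  circle, the central helix (TM3) at a smaller radius;
* an inactive state with the TM6 cytoplasmic end tilted toward TM3 so the
  3.50-6.34 C-alpha distance equals the inactive reference (8.2 A), and an
  active state solved so the same distance equals the active reference
  (13.8 A) while the 6.48 C-alpha slides 6.8 A along the bundle axis;
* TM7 tilted per state so the 5.58-7.53 hydroxyl distance matches its
  references (10.5 A inactive, 3.4 A active);
* toggle-switch side chains (Phe at 3.36, Trp at 6.48) built from ideal
  internal coordinates at prescribed (chi1, chi2), so measured dihedrals are
  exact by construction;
* an N-terminal probe phenylalanine inserted into the pocket in the inactive
  state and extruded in the active state, plus ECL2 and 3.25 ring partners;
* TM1/TM2 shifted inward in the active state.

State geometry is solved numerically (Brent / least squares) at build time;
builds are fully deterministic. Trajectories interpolate linearly in
Cartesian space between the two state coordinate sets, with optional
Gaussian coordinate noise and an optional direct chi-jitter mode that
rotates the toggle side chains about their chi bond axes.

No physical realism is attempted beyond geometry: there is no force field,
no sterics, and no membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import GpcrStateError
from .geometry import dihedral, ring_centroid, atom_distance
from .structure_model import (
    AtomRecord,
    FrameSeries,
    GenericNumberMap,
    Residue,
    Structure,
    TMSegmentTable,
)

__all__ = [
    "BundleParams",
    "TrajectorySchedule",
    "GroundTruth",
    "build_bundle",
    "generate_trajectory",
    "make_two_residue_probe",
    "cb1_like_map",
    "cb1_like_segments",
    "place_atom",
]

# ---------------------------------------------------------------------------
# Internal-coordinate atom placement (NeRF)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor), bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone (N, CA, C, O, CB) for n_res residues."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.2)
    c0 = ca0 + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = res[-1]
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, _PSI)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, 1.458, 121.7, _OMEGA)
        c_next = place_atom(prev["C"], n_next, ca_next, 1.525, 111.2, _PHI)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for r in res:
        # carbonyl O roughly anti to the next N (helical psi)
        r["O"] = place_atom(r["N"], r["CA"], r["C"], 1.231, 120.5, _PSI + 180.0)
        r["CB"] = place_atom(r["C"], r["N"], r["CA"], 1.530, 110.4, 122.6)
    return res


def _attach_phe_ring(atoms: dict[str, np.ndarray], chi1: float, chi2: float, tyr: bool = False) -> dict[str, np.ndarray]:
    """Benzene ring (and Tyr OH) built at the given chi angles."""
    out = {}
    cg = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.50, 113.8, chi1)
    out["CG"] = cg
    cd1 = place_atom(atoms["CA"], atoms["CB"], cg, 1.39, 120.8, chi2)
    cd2 = place_atom(atoms["CA"], atoms["CB"], cg, 1.39, 120.8, chi2 + 180.0)
    out["CD1"], out["CD2"] = cd1, cd2
    ce1 = place_atom(atoms["CB"], cg, cd1, 1.39, 120.0, 180.0)
    ce2 = place_atom(atoms["CB"], cg, cd2, 1.39, 120.0, 180.0)
    out["CE1"], out["CE2"] = ce1, ce2
    out["CZ"] = place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
    if tyr:
        out["OH"] = place_atom(cd1, ce1, out["CZ"], 1.38, 120.0, 180.0)
    return out


def _attach_trp_ring(atoms: dict[str, np.ndarray], chi1: float, chi2: float) -> dict[str, np.ndarray]:
    """Indole ring at the given chi angles (chi2 on CD1)."""
    out = {}
    cg = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.50, 113.6, chi1)
    out["CG"] = cg
    cd1 = place_atom(atoms["CA"], atoms["CB"], cg, 1.37, 127.0, chi2)
    cd2 = place_atom(atoms["CA"], atoms["CB"], cg, 1.43, 126.6, chi2 + 180.0)
    out["CD1"], out["CD2"] = cd1, cd2
    ne1 = place_atom(atoms["CB"], cg, cd1, 1.38, 110.1, 180.0)
    ce2 = place_atom(atoms["CB"], cg, cd2, 1.40, 107.3, 180.0)
    out["NE1"], out["CE2"] = ne1, ce2
    out["CZ2"] = place_atom(cg, cd2, ce2, 1.40, 122.3, 180.0)
    out["CE3"] = place_atom(ne1, ce2, cd2, 1.40, 133.9, 180.0)
    out["CH2"] = place_atom(cd2, ce2, out["CZ2"], 1.37, 117.4, 0.0)
    out["CZ3"] = place_atom(ce2, cd2, out["CE3"], 1.40, 118.6, 0.0)
    return out


# ---------------------------------------------------------------------------
# CB1-like bundle layout
# ---------------------------------------------------------------------------

# Inclusive residue ranges per TM helix (CB1-like author numbering).
_TM_RANGES = {1: (110, 140), 2: (145, 177), 3: (186, 220), 4: (234, 260),
              5: (275, 305), 6: (335, 363), 7: (372, 400)}
# Residue number of the x.50 anchor per helix; label h.pp -> anchor + (pp-50).
_ANCHOR_50 = {1: 134, 2: 163, 3: 214, 4: 248, 5: 286, 6: 358, 7: 394}
# Helices whose residue numbers increase toward the cytoplasm (-z).
_DOWN_HELICES = {1, 3, 5, 7}
# Full side chains built for these residues; everything else is Ala-like.
_SPECIAL = {
    200: ("PHE", "phe"), 356: ("TRP", "trp"), 294: ("TYR", "tyr"),
    397: ("TYR", "tyr"), 174: ("PHE", "phe"), 189: ("PHE", "phe"),
}
# Named but side-chain-truncated residues (as in partially modelled density).
_NAMED_STUBS = {214: "ARG", 342: "ALA", 120: "ALA", 380: "ALA",
                286: "LEU", 204: "VAL", 352: "LEU"}
# Residue whose CB is spun to face the bundle center, per helix.
_FACING = {1: 120, 2: 174, 3: 200, 4: 247, 5: 294, 6: 356, 7: 397}


def cb1_like_map(chain_id: str = "A") -> GenericNumberMap:
    """Generic-number map matching the synthetic bundle's numbering."""
    entries: dict[str, tuple[str, int]] = {}
    for h, (lo, hi) in _TM_RANGES.items():
        for seq in range(lo, hi + 1):
            pos = 50 + seq - _ANCHOR_50[h]
            entries[f"{h}.{pos:02d}"] = (chain_id, seq)
    entries["N-term"] = (chain_id, 102)
    entries["ECL2"] = (chain_id, 268)
    return GenericNumberMap(entries)


def cb1_like_segments(chain_id: str = "A") -> TMSegmentTable:
    return TMSegmentTable(
        {f"TM{h}": (chain_id, lo, hi) for h, (lo, hi) in _TM_RANGES.items()}
    )


@dataclass
class BundleParams:
    """Geometry of the synthetic bundle and its two states.

    The reference distances are the indicator values the built states must
    reproduce (checked to 0.1 A after each build): 3.50-6.34 C-alpha and
    5.58-7.53 hydroxyl distances per state, and the 6.48 C-alpha slide
    between states measured with TM3 aligned.
    """

    chain_id: str = "A"
    radius: float = 11.0          # A, circle of helix axes
    tm3_radius: float = 5.0       # A, TM3 sits nearer the bundle core
    z_centers: dict[int, float] = field(default_factory=lambda: {
        1: 0.0, 2: 0.0, 3: 3.0, 4: 0.0, 5: 0.0, 6: 0.0, 7: 0.0})
    # Toggle chi targets per state. The 3.36 Phe changes rotamer on
    # activation (and packs against the 6.48 Trp only in the inactive
    # state); the 6.48 Trp keeps one rotamer in both reference states.
    chi1_336: dict[str, float] = field(default_factory=lambda: {"A": -60.0, "I": 150.0})
    chi2_336: dict[str, float] = field(default_factory=lambda: {"A": 90.0, "I": 90.0})
    chi1_648: dict[str, float] = field(default_factory=lambda: {"A": 60.0, "I": 60.0})
    chi2_648: dict[str, float] = field(default_factory=lambda: {"A": 90.0, "I": 90.0})
    # indicator references the build must reproduce
    ref_tm3_tm6: dict[str, float] = field(default_factory=lambda: {"A": 13.8, "I": 8.2})
    ref_y_y: dict[str, float] = field(default_factory=lambda: {"A": 3.4, "I": 10.5})
    slide_648: float = 6.8        # A, 6.48 C-alpha displacement between states
    tm1_inward: float = 1.5       # A, active-state inward shift of TM1
    tm2_inward: float = 2.0       # A, active-state inward shift of TM2


@dataclass
class TrajectorySchedule:
    """Held-state segments, linear bridges between them, and noise levels."""

    segments: list[tuple[str, int]]      # (state in {A, I, intermediate}, frames)
    interpolation_frames: int = 0        # bridge frames between segments
    noise_sigma: float = 0.0             # A, iid Gaussian per coordinate
    chi_jitter_sigma: float = 0.0        # deg, direct toggle chi jitter
    frame_interval_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments or sum(n for _, n in self.segments) < 1:
            raise ValueError("schedule must contain at least one frame")
        for label, n in self.segments:
            if label not in ("A", "I", "intermediate"):
                raise ValueError(f"unknown state label {label!r}")
            if n < 1:
                raise ValueError("segment frame counts must be >= 1")
        if self.noise_sigma < 0 or self.chi_jitter_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-frame labels recorded by the generator (the test oracle)."""

    state_labels: list[str]        # A / I / intermediate / transition
    toggle_labels: list[str]       # active / inactive / unassigned
    transition_frames: list[int]   # midpoints (frame index) of each bridge

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frame": range(len(self.state_labels)),
             "state": self.state_labels,
             "toggle": self.toggle_labels}
        ).to_csv(path, sep="\t", index=False)


# -- helpers ----------------------------------------------------------------

def _rot_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def _align_u_to_v(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 deg about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _rot_axis(perp, math.pi)
    axis = np.cross(u, v)
    return _rot_axis(axis, math.acos(max(-1.0, min(1.0, c))))


class _Helix:
    """Mutable helper holding one helix's residues during construction."""

    def __init__(self, index: int, residues: list[tuple[int, str, dict[str, np.ndarray]]]):
        self.index = index
        self.residues = residues  # (resseq, res_name, {atom: pos})

    def transform(self, rot: np.ndarray | None = None, trans: np.ndarray | None = None,
                  center: np.ndarray | None = None) -> None:
        c = np.zeros(3) if center is None else center
        for _, _, atoms in self.residues:
            for name in atoms:
                p = atoms[name]
                if rot is not None:
                    p = rot @ (p - c) + c
                if trans is not None:
                    p = p + trans
                atoms[name] = p

    def atom(self, resseq: int, name: str) -> np.ndarray:
        for seq, _, atoms in self.residues:
            if seq == resseq:
                return atoms[name]
        raise KeyError((resseq, name))

    def ca_coords(self) -> np.ndarray:
        return np.array([atoms["CA"] for _, _, atoms in self.residues])

    def copy(self) -> "_Helix":
        return _Helix(self.index, [(s, n, {k: v.copy() for k, v in a.items()})
                                   for s, n, a in self.residues])


def _build_helix(h: int, params: BundleParams, chi_overrides: dict[int, tuple[float, float]]) -> _Helix:
    lo, hi = _TM_RANGES[h]
    n_res = hi - lo + 1
    backbone = _helix_backbone(n_res)
    residues: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for i, seq in enumerate(range(lo, hi + 1)):
        atoms = dict(backbone[i])
        name = "ALA"
        if seq in _SPECIAL:
            name, kind = _SPECIAL[seq]
            chi1, chi2 = chi_overrides.get(seq, (-60.0, 90.0))
            if kind == "trp":
                atoms.update(_attach_trp_ring(atoms, chi1, chi2))
            else:
                atoms.update(_attach_phe_ring(atoms, chi1, chi2, tyr=(kind == "tyr")))
        elif seq in _NAMED_STUBS:
            name = _NAMED_STUBS[seq]
        residues.append((seq, name, atoms))
    helix = _Helix(h, residues)

    # orient: helix axis (first->last CA) to +/- z
    cas = helix.ca_coords()
    axis = cas[-1] - cas[0]
    target = np.array([0.0, 0.0, -1.0 if h in _DOWN_HELICES else 1.0])
    helix.transform(rot=_align_u_to_v(axis, target), center=cas.mean(axis=0))

    # place on the bundle circle
    theta = math.radians((h - 1) * 360.0 / 7.0)
    r = params.tm3_radius if h == 3 else params.radius
    pos = np.array([r * math.cos(theta), r * math.sin(theta), params.z_centers.get(h, 0.0)])
    cas = helix.ca_coords()
    helix.transform(trans=pos - cas.mean(axis=0))

    # spin about own axis so the facing residue's CB points at the bundle core
    face = helix.atom(_FACING[h], "CB") - helix.atom(_FACING[h], "CA")
    face_h = np.array([face[0], face[1]])
    want = -np.array([pos[0], pos[1]])
    if np.linalg.norm(face_h) > 1e-9 and np.linalg.norm(want) > 1e-9:
        a1 = math.atan2(face_h[1], face_h[0])
        a2 = math.atan2(want[1], want[0])
        helix.transform(rot=_rot_axis(np.array([0.0, 0.0, 1.0]), a2 - a1),
                        center=helix.ca_coords().mean(axis=0))
    return helix


def _free_phe(resseq: int, centroid_target: np.ndarray, chain_id: str) -> tuple[int, str, dict[str, np.ndarray]]:
    """An isolated phenylalanine whose ring centroid sits at the target."""
    backbone = _helix_backbone(1)[0]
    atoms = dict(backbone)
    atoms.update(_attach_phe_ring(atoms, -60.0, 90.0))
    ring = np.mean([atoms[n] for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")], axis=0)
    shift = np.asarray(centroid_target, dtype=float) - ring
    return (resseq, "PHE", {k: v + shift for k, v in atoms.items()})


def _hinge_tilt(helix: _Helix, tilt_deg: float, toward: np.ndarray) -> None:
    """Rotate a helix about a horizontal axis through its extracellular end.

    Positive tilt moves the cytoplasmic end in the horizontal ``toward``
    direction.
    """
    cas = helix.ca_coords()
    top = cas[np.argmax(cas[:, 2])]
    toward = np.array([toward[0], toward[1], 0.0])
    toward /= np.linalg.norm(toward)
    axis = np.cross(np.array([0.0, 0.0, -1.0]), toward)  # so +tilt moves bottom toward
    helix.transform(rot=_rot_axis(axis, math.radians(tilt_deg)), center=top)


def _solve_tm6(helices: dict[int, _Helix], params: BundleParams) -> dict[str, _Helix]:
    """Solve the TM6 placement for both states.

    Inactive: hinge tilt toward TM3 reproducing the inactive 3.50-6.34
    distance. Active: hinge tilt plus an axial slide, solved jointly for the
    active 3.50-6.34 distance and the 6.48 C-alpha displacement from the
    inactive state.
    """
    ca_350 = helices[3].atom(214, "CA")
    base = helices[6]
    toward = np.array([ca_350[0], ca_350[1], 0.0]) - np.array(
        [base.ca_coords().mean(axis=0)[0], base.ca_coords().mean(axis=0)[1], 0.0])

    def tm6_at(tilt: float, dz: float) -> _Helix:
        h = base.copy()
        _hinge_tilt(h, tilt, toward)
        h.transform(trans=np.array([0.0, 0.0, dz]))
        return h

    def d_350_634(tilt: float, dz: float) -> float:
        return atom_distance(ca_350, tm6_at(tilt, dz).atom(342, "CA"))

    # distance vs tilt is non-monotone (the helix bottom sweeps past TM3);
    # bracket on the near side of the minimum
    hi = 50.0
    for cand in np.arange(2.0, 50.0, 2.0):
        if d_350_634(float(cand), 0.0) - params.ref_tm3_tm6["I"] < 0:
            hi = float(cand)
            break
    tilt_i = brentq(lambda t: d_350_634(t, 0.0) - params.ref_tm3_tm6["I"], 0.0, hi, xtol=1e-10)
    tm6_i = tm6_at(tilt_i, 0.0)
    ca_648_i = tm6_i.atom(356, "CA")

    def residuals(x):
        tilt, dz = x
        h = tm6_at(tilt, dz)
        return [
            atom_distance(ca_350, h.atom(342, "CA")) - params.ref_tm3_tm6["A"],
            atom_distance(ca_648_i, h.atom(356, "CA")) - params.slide_648,
        ]

    sol = least_squares(residuals, x0=[max(tilt_i - 8.0, -2.0), -5.0],
                        bounds=([-10.0, -9.0], [50.0, 0.0]), xtol=1e-12, ftol=1e-12)
    if np.max(np.abs(sol.fun)) > 0.05:
        raise GpcrStateError(
            f"TM6 state solve failed to meet targets (residuals {sol.fun})")
    tm6_a = tm6_at(sol.x[0], sol.x[1])
    return {"I": tm6_i, "A": tm6_a}


def _solve_tm7(helices: dict[int, _Helix], params: BundleParams, state: str) -> _Helix:
    """Move TM7 so the 5.58-7.53 hydroxyl distance hits the state target.

    TM7 is first slid along the bundle axis so the two hydroxyls are level
    (the TM7 distortion of activation is dominated by its cytoplasmic half),
    then its cytoplasmic end is hinge-tilted toward Y5.58; the tilt angle is
    solved by bracketing.
    """
    oh_294 = helices[5].atom(294, "OH")
    shifted = helices[7].copy()
    dz0 = oh_294[2] - shifted.atom(397, "OH")[2]
    shifted.transform(trans=np.array([0.0, 0.0, dz0]))
    toward = oh_294 - shifted.atom(397, "OH")

    def dist(tilt: float) -> float:
        h = shifted.copy()
        _hinge_tilt(h, tilt, toward)
        return atom_distance(oh_294, h.atom(397, "OH"))

    target = params.ref_y_y[state]
    grid = np.arange(-40.0, 70.0, 2.0)
    vals = [dist(float(t)) - target for t in grid]
    bracket = None
    for (t0, f0), (t1, f1) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if f0 * f1 <= 0:
            bracket = (float(t0), float(t1))
            break
    if bracket is None:
        raise GpcrStateError(f"cannot bracket TM7 tilt for target {target} A")
    tilt = brentq(lambda t: dist(t) - target, *bracket, xtol=1e-10)
    h = shifted
    _hinge_tilt(h, tilt, toward)
    return h


def build_bundle(params: BundleParams | None = None, state: str = "A") -> Structure:
    """Build the synthetic bundle in state ``"A"`` (active) or ``"I"`` (inactive).

    The returned structure carries CB1-like author numbering addressed by
    :func:`cb1_like_map` and :func:`cb1_like_segments`. Indicator targets
    (3.50-6.34, 5.58-7.53) are verified to 0.1 A after the build.
    """
    if params is None:
        params = BundleParams()
    if state not in ("A", "I"):
        raise ValueError(f"state must be 'A' or 'I', got {state!r}")

    chi = {
        200: (params.chi1_336[state], params.chi2_336[state]),
        356: (params.chi1_648[state], params.chi2_648[state]),
        294: (180.0, 90.0), 397: (180.0, 90.0),
        174: (-60.0, 90.0), 189: (-60.0, 90.0),
    }
    helices = {h: _build_helix(h, params, chi) for h in range(1, 8)}

    helices[6] = _solve_tm6(helices, params)[state]
    helices[7] = _solve_tm7(helices, params, state)
    if state == "A":
        for h, amount in ((1, params.tm1_inward), (2, params.tm2_inward)):
            c = helices[h].ca_coords().mean(axis=0)
            inward = -np.array([c[0], c[1], 0.0])
            inward /= np.linalg.norm(inward)
            helices[h].transform(trans=amount * inward)

    # loop/terminal probe residues
    ring_189 = np.mean([helices[3].atom(189, n) for n in
                        ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")], axis=0)
    theta_ecl2 = math.radians(4.5 * 360.0 / 7.0)  # over the TM4/TM5 gap
    ecl2_pos = np.array([7.0 * math.cos(theta_ecl2), 7.0 * math.sin(theta_ecl2), 23.0])
    if state == "I":
        nt_pos = 0.5 * (ring_189 + ecl2_pos) + np.array([0.0, 0.0, 1.0])
    else:
        nt_pos = np.array([26.0, 0.0, 26.0])

    extras = [_free_phe(102, nt_pos, params.chain_id),
              _free_phe(268, ecl2_pos, params.chain_id)]

    entries: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for h in range(1, 8):
        entries.extend(helices[h].residues)
    entries.extend(extras)
    entries.sort(key=lambda t: t[0])

    atom_order = ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE1",
                  "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2", "OH"]
    residues = []
    for seq, name, atoms in entries:
        recs = [AtomRecord(an, "N" if an.startswith("N") else ("O" if an.startswith("O") else "C"),
                           atoms[an])
                for an in atom_order if an in atoms]
        residues.append(Residue(params.chain_id, seq, "", name, recs))
    s = Structure(f"synthetic-{state}", residues)

    _check_build(s, params, state)
    return s


def _check_build(s: Structure, params: BundleParams, state: str) -> None:
    d36 = atom_distance(s.get_residue(params.chain_id, 214).atom("CA").position,
                        s.get_residue(params.chain_id, 342).atom("CA").position)
    dyy = atom_distance(s.get_residue(params.chain_id, 294).atom("OH").position,
                        s.get_residue(params.chain_id, 397).atom("OH").position)
    if abs(d36 - params.ref_tm3_tm6[state]) > 0.1:
        raise GpcrStateError(
            f"built state {state}: 3.50-6.34 distance {d36:.3f} misses "
            f"{params.ref_tm3_tm6[state]}")
    if abs(dyy - params.ref_y_y[state]) > 0.1:
        raise GpcrStateError(
            f"built state {state}: 5.58-7.53 distance {dyy:.3f} misses "
            f"{params.ref_y_y[state]}")
    for seq, (chi1_t, chi2_t) in ((200, (params.chi1_336[state], params.chi2_336[state])),
                                  (356, (params.chi1_648[state], params.chi2_648[state]))):
        res = s.get_residue(params.chain_id, seq)
        from .geometry import angle_difference, chi_angles

        chi1, chi2 = chi_angles(res)
        if angle_difference(chi1, chi1_t) > 1e-3 or (
            chi2 is not None and angle_difference(chi2, chi2_t) > 1e-3
        ):
            raise GpcrStateError(f"residue {seq}: built chi differs from target")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_STATE_T = {"A": 0.0, "intermediate": 0.5, "I": 1.0}

# atom index bookkeeping for chi-jitter: side-chain atoms distal to each chi bond
_CHI1_DISTAL = ("CG", "CD1", "CD2", "NE1", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2", "OH")
_CHI2_DISTAL = ("CD1", "CD2", "NE1", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2", "OH")


def _atom_indices(s: Structure, resseq: int, names: tuple[str, ...], chain_id: str) -> list[int]:
    idx, i = [], 0
    for r in s.residues:
        for a in r.atoms:
            if r.chain_id == chain_id and r.res_seq == resseq and a.atom_name in names:
                idx.append(i)
            i += 1
    return idx


def _chi_jitter(coords: np.ndarray, s: Structure, resseq: int, chain_id: str,
                which: int, delta_deg: float) -> None:
    """Rotate the distal side-chain atoms of one residue about its chi axis."""
    i = 0
    pos = {}
    for r in s.residues:
        for a in r.atoms:
            if r.chain_id == chain_id and r.res_seq == resseq:
                pos[a.atom_name] = i
            i += 1
    if which == 1:
        p_axis0, p_axis1 = coords[pos["CA"]], coords[pos["CB"]]
        distal = [pos[n] for n in _CHI1_DISTAL if n in pos]
    else:
        p_axis0, p_axis1 = coords[pos["CB"]], coords[pos["CG"]]
        distal = [pos[n] for n in _CHI2_DISTAL if n in pos]
    axis = p_axis1 - p_axis0
    rot = _rot_axis(axis, math.radians(delta_deg))
    coords[distal] = (coords[distal] - p_axis1) @ rot.T + p_axis1


def generate_trajectory(
    params: BundleParams | None = None,
    sched: TrajectorySchedule | None = None,
) -> tuple[FrameSeries, GroundTruth]:
    """Generate a frame series following the schedule, with ground truth.

    Held segments repeat a state's coordinates; bridges between segments with
    different labels interpolate linearly in Cartesian space. Gaussian
    coordinate noise and toggle chi jitter are applied per frame from a
    seeded generator; the same seed reproduces the series bit-identically.
    """
    if params is None:
        params = BundleParams()
    if sched is None:
        sched = TrajectorySchedule(segments=[("A", 10)])
    rng = np.random.default_rng(sched.seed)

    s_a = build_bundle(params, "A")
    s_i = build_bundle(params, "I")
    c_a, c_i = s_a.coordinates(), s_i.coordinates()
    topo = s_a.copy()
    topo.id = "synthetic-trajectory"

    ts: list[float] = []
    state_labels: list[str] = []
    transition_frames: list[int] = []
    for k, (label, n) in enumerate(sched.segments):
        if k > 0 and sched.interpolation_frames > 0 and sched.segments[k - 1][0] != label:
            t0 = _STATE_T[sched.segments[k - 1][0]]
            t1 = _STATE_T[label]
            bridge = np.linspace(t0, t1, sched.interpolation_frames + 2)[1:-1]
            transition_frames.append(len(ts) + sched.interpolation_frames // 2)
            for t in bridge:
                ts.append(float(t))
                state_labels.append("transition")
        ts.extend([_STATE_T[label]] * n)
        state_labels.extend([label] * n)

    toggle_truth = {"A": "active", "I": "inactive", "intermediate": "unassigned",
                    "transition": "unassigned"}
    toggle_labels = [toggle_truth[l] for l in state_labels]

    n_frames = len(ts)
    frames = np.empty((n_frames, c_a.shape[0], 3))
    for i, t in enumerate(ts):
        coords = (1.0 - t) * c_a + t * c_i
        if sched.chi_jitter_sigma > 0:
            for resseq, which in ((200, 1), (356, 2)):
                _chi_jitter(coords, topo, resseq, params.chain_id, which,
                            float(rng.normal(0.0, sched.chi_jitter_sigma)))
        if sched.noise_sigma > 0:
            coords = coords + rng.normal(0.0, sched.noise_sigma, coords.shape)
        frames[i] = coords

    times = sched.frame_interval_ns * np.arange(1, n_frames + 1)
    fs = FrameSeries(topology=topo, frames=frames, times=times)
    gt = GroundTruth(state_labels=state_labels, toggle_labels=toggle_labels,
                     transition_frames=transition_frames)
    return fs, gt


# ---------------------------------------------------------------------------
# Micro-fixtures
# ---------------------------------------------------------------------------

def make_two_residue_probe(d: float, atoms_per_residue: int = 3) -> Structure:
    """Two residues whose closest heavy-atom pair is exactly ``d`` apart.

    Extra atoms trail away from the partner residue so only the leading pair
    is within contact range. Sequence separation is large enough that no
    backbone exclusion applies.
    """
    if d <= 0:
        raise ValueError("d must be positive")

    def make(resseq: int, origin: np.ndarray, away: np.ndarray) -> Residue:
        atoms = [AtomRecord("CB", "C", origin)]
        for k in range(1, atoms_per_residue):
            atoms.append(AtomRecord(f"C{k}", "C", origin + 8.0 * k * away))
        return Residue("A", resseq, "", "ALA", atoms)

    r1 = make(1, np.array([0.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    r2 = make(20, np.array([d, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    return Structure("probe", [r1, r2])
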