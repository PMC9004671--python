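"""Superposition, dihedral, and distance kernel tests.

Independent oracles: Biopython's SVDSuperimposer and calc_dihedral, a
random-rotation sampler for the minimal-RMSD property, and direct vector
arithmetic.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrstate import atom_distance, chi_angles, dihedral, ring_centroid, superpose
from gpcrstate.errors import (
    GeometryError,
    IncompleteSideChainError,
    NoChiAngleError,
)
from gpcrstate.structure_model import AtomRecord, Residue
from gpcrstate.synthetic_data import _attach_trp_ring, _helix_backbone, place_atom

finite = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self, rng):
        pts = rng.normal(size=(8, 3))
        _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_rmsd_zero(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rot = _random_rotation(rng)
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        transform, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.apply(pts), moved, atol=1e-8)

    def test_small_triangle_matches_numerical_minimizer(self):
        """Brute-force rotation grid + local refinement as the oracle."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        mobile = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        reference = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.5]], dtype=float)

        def rmsd_for(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            a = (mobile - mobile.mean(0)) @ rot.T
            b = reference - reference.mean(0)
            return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))

        best = np.inf
        rng = np.random.default_rng(7)
        for _ in range(400):
            x0 = rng.uniform(-np.pi, np.pi, 3)
            res = minimize(rmsd_for, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        _, rmsd = superpose(mobile, reference)
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_beats_random_rotations(self, rng):
        """Kabsch RMSD is minimal over 1000 random rigid placements."""
        mobile = rng.normal(size=(12, 3)) * 4
        reference = mobile + rng.normal(size=(12, 3)) * 0.8
        _, best = superpose(mobile, reference)
        mc, rc = mobile.mean(0), reference.mean(0)
        for _ in range(1000):
            rot = _random_rotation(rng)
            trial = np.sqrt(
                np.mean(np.sum(((mobile - mc) @ rot.T - (reference - rc)) ** 2, axis=1))
            )
            assert best <= trial + 1e-9

    def test_matches_svd_superimposer(self, rng):
        SVDSuperimposer = pytest.importorskip("Bio.SVDSuperimposer").SVDSuperimposer
        for _ in range(25):
            a = rng.normal(size=(6, 3)) * 4
            b = rng.normal(size=(6, 3)) * 4
            _, rmsd = superpose(a, b)
            sup = SVDSuperimposer()
            sup.set(b, a)
            sup.run()
            assert rmsd == pytest.approx(sup.get_rms(), abs=1e-9)

    def test_too_few_points_raise(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_raise(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(GeometryError):
            superpose(line, line)


class TestDistance:
    def test_three_four_five(self):
        assert atom_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)

    def test_coincident(self):
        assert atom_distance([1, 1, 1], [1, 1, 1]) == 0.0

    @given(p=point, q=point)
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_formula(self, p, q):
        direct = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert atom_distance(p, q) == pytest.approx(direct, abs=1e-12)

    @given(p=point, q=point, r=point)
    @settings(max_examples=50, deadline=None)
    def test_triangle_inequality(self, p, q, r):
        assert atom_distance(p, r) <= atom_distance(p, q) + atom_distance(q, r) + 1e-9


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_perpendicular_sign_convention(self):
        # frozen from the Biopython calc_dihedral oracle
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)) == pytest.approx(90.0)

    def test_matches_biopython_on_random_inputs(self, rng):
        vectors = pytest.importorskip("Bio.PDB.vectors")
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            expected = math.degrees(
                vectors.calc_dihedral(*[vectors.Vector(*p) for p in pts])
            )
            diff = abs((dihedral(*pts) - expected + 180) % 360 - 180)
            assert diff < 1e-9

    def test_invariant_under_order_reversal(self, rng):
        # a torsion reads the same from either end of the chain
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            assert dihedral(*pts) == pytest.approx(dihedral(*pts[::-1]), abs=1e-9)

    def test_antisymmetric_under_mirror_reflection(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            fwd = dihedral(*pts)
            if abs(abs(fwd) - 180.0) < 1e-9:
                continue  # +180 wraps to itself
            assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


class TestRingCentroid:
    def test_regular_hexagon_centroid_is_center(self):
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = [
            AtomRecord(n, "C", [math.cos(k * math.pi / 3), math.sin(k * math.pi / 3), 0.0])
            for k, n in enumerate(names)
        ]
        res = Residue("A", 1, "", "PHE", atoms)
        np.testing.assert_allclose(ring_centroid(res), [0, 0, 0], atol=1e-12)

    def test_degenerate_ring_at_single_point(self):
        atoms = [
            AtomRecord(n, "C", [1.0, 2.0, 3.0])
            for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        ]
        res = Residue("A", 1, "", "PHE", atoms)
        np.testing.assert_allclose(ring_centroid(res), [1, 2, 3])

    def test_missing_ring_atom_raises(self):
        atoms = [
            AtomRecord(n, "C", [float(k), 0, 0])
            for k, n in enumerate(("CG", "CD1", "CD2", "CE1", "CE2"))
        ]
        res = Residue("A", 1, "", "PHE", atoms)
        with pytest.raises(IncompleteSideChainError, match="CZ"):
            ring_centroid(res)


class TestChiAngles:
    def _trp_at(self, chi1, chi2):
        backbone = _helix_backbone(1)[0]
        atoms = dict(backbone)
        atoms.update(_attach_trp_ring(atoms, chi1, chi2))
        return Residue("A", 1, "", "TRP", [AtomRecord(k, "C", v) for k, v in atoms.items()])

    def test_trp_built_at_target_angles(self):
        res = self._trp_at(-60.0, 90.0)
        chi1, chi2 = chi_angles(res)
        assert chi1 == pytest.approx(-60.0, abs=1e-3)
        assert chi2 == pytest.approx(90.0, abs=1e-3)

    def test_phe_trans_chi1(self):
        from gpcrstate.synthetic_data import _attach_phe_ring

        backbone = _helix_backbone(1)[0]
        atoms = dict(backbone)
        atoms.update(_attach_phe_ring(atoms, 180.0, 90.0))
        res = Residue("A", 1, "", "PHE", [AtomRecord(k, "C", v) for k, v in atoms.items()])
        chi1, _ = chi_angles(res)
        assert abs(abs(chi1) - 180.0) < 1e-3

    def test_alanine_has_no_chi(self):
        backbone = _helix_backbone(1)[0]
        res = Residue("A", 1, "", "ALA", [AtomRecord(k, "C", v) for k, v in backbone.items()])
        with pytest.raises(NoChiAngleError):
            chi_angles(res)

    def test_missing_gamma_atom_raises(self):
        backbone = _helix_backbone(1)[0]
        res = Residue("A", 1, "", "PHE", [AtomRecord(k, "C", v) for k, v in backbone.items()])
        with pytest.raises(IncompleteSideChainError):
            chi_angles(res)


def test_place_atom_reproduces_internal_coordinates(rng):
    """NeRF placement and the dihedral routine are mutually consistent."""
    for _ in range(50):
        a, b, c = rng.normal(size=(3, 3)) * 3
        if np.linalg.norm(b - c) < 0.5 or np.linalg.norm(a - b) < 0.5:
            continue
        bond = rng.uniform(1.0, 2.0)
        angle = rng.uniform(60, 150)
        torsion = rng.uniform(-179, 180)
        d = place_atom(a, b, c, bond, angle, torsion)
        assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
        assert dihedral(a, b, c, d) == pytest.approx(torsion, abs=1e-6)
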