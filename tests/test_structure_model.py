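"""PDB I/O, frame series, and numbering-table behavior."""

import numpy as np
import pytest

from gpcrstate import (
    GenericNumberMap,
    Structure,
    TMSegmentTable,
    read_frames,
    read_pdb,
    resolve_label,
    write_pdb,
)
from gpcrstate.errors import (
    EmptyInputError,
    LookupError_,
    PDBFormatError,
    TopologyMismatchError,
)
from gpcrstate.structure_model import AtomRecord, FrameSeries, Residue, write_frames


def test_single_atom_round_trip(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        "END\n"
    )
    s = read_pdb(path)
    assert len(s) == 1
    assert s.residues[0].atoms[0].atom_name == "CA"
    np.testing.assert_allclose(s.residues[0].atoms[0].position, [1.0, 2.0, 3.0])


def test_write_read_round_trip_preserves_coordinates(tmp_path, bundle_active):
    p1 = tmp_path / "a.pdb"
    p2 = tmp_path / "b.pdb"
    write_pdb(bundle_active, p1)
    s1 = read_pdb(p1)
    write_pdb(s1, p2)
    s2 = read_pdb(p2)
    assert s1.atom_count() == bundle_active.atom_count() == s2.atom_count()
    # the written file is on the 3-decimal PDB grid; a second pass is exact
    np.testing.assert_allclose(
        s1.coordinates(), bundle_active.coordinates(), atol=5.1e-4
    )
    np.testing.assert_array_equal(s1.coordinates(), s2.coordinates())


def test_round_trip_matches_independent_reader(tmp_path, bundle_inactive):
    gemmi = pytest.importorskip("gemmi")
    path = tmp_path / "bundle.pdb"
    write_pdb(bundle_inactive, path)
    st = gemmi.read_structure(str(path))
    coords = np.array(
        [[a.pos.x, a.pos.y, a.pos.z] for m in st for ch in m for r in ch for a in r]
    )
    ours = read_pdb(path).coordinates()
    np.testing.assert_array_equal(coords, ours)


def test_altloc_policy_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
        "ATOM      3  CB AALA A   1       3.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      4  CB BALA A   1       4.000   0.000   0.000  0.50  0.00           C\n"
        "END\n"
    )
    s = read_pdb(path)
    res = s.residues[0]
    assert len(res.atoms) == 2
    assert res.atom("CA").position[0] == pytest.approx(2.0)  # higher occupancy
    assert res.atom("CB").position[0] == pytest.approx(3.0)  # tie -> altloc A


def test_unparseable_coordinate_names_line(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CB  ALA A   1       xxx     2.000   3.000  1.00  0.00           C\n"
    )
    with pytest.raises(PDBFormatError, match="line 2"):
        read_pdb(path)


def test_no_atom_records_is_empty_input(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(EmptyInputError):
        read_pdb(path)


def test_write_empty_structure_raises(tmp_path):
    with pytest.raises(EmptyInputError):
        write_pdb(Structure("empty", []), tmp_path / "x.pdb")


def test_write_out_of_range_coordinate_raises(tmp_path):
    s = Structure(
        "big",
        [Residue("A", 1, "", "ALA", [AtomRecord("CA", "C", [99999.0, 0, 0])])],
    )
    with pytest.raises(ValueError):
        write_pdb(s, tmp_path / "x.pdb")


def test_hydrogens_retained_but_flagged(tmp_path):
    path = tmp_path / "h.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  HA  ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
        "END\n"
    )
    res = read_pdb(path).residues[0]
    assert len(res.atoms) == 2
    assert [a.atom_name for a in res.heavy_atoms()] == ["CA"]


class TestFrames:
    def _multimodel(self, tmp_path, n_models, shift=0.0):
        lines = []
        for m in range(1, n_models + 1):
            lines.append(f"MODEL     {m:4d}\n")
            lines.append(
                f"ATOM      1  CA  ALA A   1    {1.0 + shift * (m - 1):8.3f}"
                f"{2.0:8.3f}{3.0:8.3f}  1.00  0.00           C\n"
            )
            lines.append("ENDMDL\n")
        lines.append("END\n")
        path = tmp_path / "mm.pdb"
        path.write_text("".join(lines))
        return path

    def test_three_models_default_times(self, tmp_path):
        fs = read_frames(self._multimodel(tmp_path, 3))
        assert len(fs) == 3
        np.testing.assert_allclose(fs.times, [1.0, 2.0, 3.0])

    def test_single_model(self, tmp_path):
        fs = read_frames(self._multimodel(tmp_path, 1))
        assert len(fs) == 1

    def test_configurable_interval(self, tmp_path):
        fs = read_frames(self._multimodel(tmp_path, 2), frame_interval_ns=0.5)
        np.testing.assert_allclose(fs.times, [0.5, 1.0])

    def test_mismatched_atom_counts_raise(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       2.000   2.000   3.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(TopologyMismatchError):
            read_frames(path)

    def test_write_frames_round_trip(self, tmp_path, bundle_active, bundle_inactive):
        fs = FrameSeries(
            topology=bundle_active,
            frames=np.stack([bundle_active.coordinates(), bundle_inactive.coordinates()]),
            times=np.array([1.0, 2.0]),
        )
        path = tmp_path / "traj.pdb"
        write_frames(fs, path)
        back = read_frames(path)
        assert len(back) == 2
        np.testing.assert_allclose(back.frames, fs.frames, atol=5.1e-4)

    def test_times_must_increase(self, bundle_active):
        coords = bundle_active.coordinates()
        with pytest.raises(ValueError):
            FrameSeries(bundle_active, np.stack([coords, coords]), np.array([2.0, 1.0]))


class TestLabels:
    def test_resolve_known_labels(self, bundle_active, gmap):
        assert resolve_label(bundle_active, gmap, "3.36").res_seq == 200
        assert resolve_label(bundle_active, gmap, "6.48").res_seq == 356
        assert resolve_label(bundle_active, gmap, "3.36").res_name == "PHE"

    def test_unknown_label_raises(self, bundle_active, gmap):
        with pytest.raises(LookupError_, match="9.99"):
            resolve_label(bundle_active, gmap, "9.99")

    def test_mapped_but_absent_residue_raises(self, bundle_active):
        gm = GenericNumberMap({"3.36": ("Z", 1)})
        with pytest.raises(LookupError_, match="3.36"):
            resolve_label(bundle_active, gm, "3.36")

    def test_label_resolution_is_injective(self, bundle_active, gmap):
        keys = {
            resolve_label(bundle_active, gmap, label).key()
            for label in gmap.entries
        }
        assert len(keys) == len(gmap.entries)

    def test_map_tsv_round_trip(self, tmp_path, gmap):
        path = tmp_path / "map.tsv"
        gmap.to_tsv(path)
        again = GenericNumberMap.from_tsv(path)
        assert again.entries == gmap.entries


class TestSegments:
    def test_tsv_round_trip(self, tmp_path, segments):
        path = tmp_path / "segs.tsv"
        segments.to_tsv(path)
        again = TMSegmentTable.from_tsv(path)
        assert again.segments == segments.segments

    def test_requires_exactly_seven(self):
        with pytest.raises(ValueError):
            TMSegmentTable({"TM1": ("A", 1, 10)})

    def test_rejects_overlap(self, segments):
        bad = dict(segments.segments)
        bad["TM2"] = ("A", 130, 150)  # overlaps TM1 (110-140)
        with pytest.raises(ValueError, match="overlap"):
            TMSegmentTable(bad)

    def test_rejects_short_segments(self, segments):
        bad = dict(segments.segments)
        bad["TM4"] = ("A", 234, 236)
        with pytest.raises(ValueError, match=">= 4"):
            TMSegmentTable(bad)
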