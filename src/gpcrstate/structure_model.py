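"""Coordinate data model, PDB I/O and residue-numbering bookkeeping.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each an ordered list of :class:`AtomRecord`.
PDB reading and writing are delegated to :mod:`gemmi`; this module adds the
policies the analysis relies on (alternate-location resolution, hydrogen
flagging, strict round-tripping) plus the two bookkeeping tables used
throughout: the Ballesteros-Weinstein generic-number map and the
transmembrane-segment table.

Residue numbering is always the 1-based author numbering found in the PDB
file; no renumbering is ever applied silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    LookupError_,
    PDBFormatError,
    TopologyMismatchError,
    GpcrStateError,
)

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "FrameSeries",
    "GenericNumberMap",
    "TMSegmentTable",
    "read_pdb",
    "write_pdb",
    "read_frames",
    "resolve_label",
]

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass
class AtomRecord:
    """A single atom: PDB atom name, element symbol and position in A."""

    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name!r}")
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue with uniquely named atoms."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.atom_name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.key()}: {names}"
            )

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


class Structure:
    """An ordered collection of residues with unique (chain, seq, icode) keys."""

    def __init__(self, id: str, residues: Iterable[Residue]):
        self.id = id
        self.residues: list[Residue] = list(residues)
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in self.residues:
            k = r.key()
            if k in self._index:
                raise ValueError(f"duplicate residue key {k} in structure {id!r}")
            self._index[k] = r

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def get_residue(self, chain_id: str, res_seq: int, icode: str = "") -> Residue:
        try:
            return self._index[(chain_id, res_seq, icode)]
        except KeyError:
            raise LookupError_(
                f"residue ({chain_id!r}, {res_seq}, {icode!r}) not in structure "
                f"{self.id!r}"
            ) from None

    def has_residue(self, chain_id: str, res_seq: int, icode: str = "") -> bool:
        return (chain_id, res_seq, icode) in self._index

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coordinates(self) -> np.ndarray:
        """All atom positions, file order, shape (n_atoms, 3)."""
        if self.atom_count() == 0:
            return np.zeros((0, 3))
        return np.vstack([a.position for r in self.residues for a in r.atoms])

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.atom_count(), 3):
            raise TopologyMismatchError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.atom_count()} atoms"
            )
        i = 0
        for r in self.residues:
            for a in r.atoms:
                a.position = coords[i].copy()
                i += 1

    def copy(self, coords: np.ndarray | None = None) -> "Structure":
        s = Structure(
            self.id,
            [
                Residue(
                    r.chain_id,
                    r.res_seq,
                    r.icode,
                    r.res_name,
                    [AtomRecord(a.atom_name, a.element, a.position.copy()) for a in r.atoms],
                )
                for r in self.residues
            ],
        )
        if coords is not None:
            s.set_coordinates(coords)
        return s


@dataclass
class FrameSeries:
    """Fixed topology plus per-frame coordinates and times in ns."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ns, strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n_atoms = self.topology.atom_count()
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise TopologyMismatchError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{n_atoms} topology atoms"
            )
        if len(self.times) != len(self.frames):
            raise TopologyMismatchError("times and frames lengths differ")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i`` (a copy)."""
        return self.topology.copy(coords=self.frames[i])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str, source: str) -> int:
    """Pre-scan coordinate records; return the number of ATOM/HETATM lines.

    gemmi is forgiving about malformed fixed-width fields, so the scan raises
    a :class:`PDBFormatError` naming the offending line before parsing.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise PDBFormatError(f"{source}: line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"{source}: line {lineno}: unparseable {what} coordinate "
                    f"{line[lo:hi]!r}"
                ) from None
    return n


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Alternate-location policy: highest occupancy, ties broken toward 'A'.

    Deterministic single-conformer selection so downstream geometry never
    depends on file ordering of conformers.
    """
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ + 1e-9:
            best = a
        elif abs(a.occ - best.occ) <= 1e-9 and (a.altloc or "~") < (best.altloc or "~"):
            best = a
    return best


def _model_to_structure(model: gemmi.Model, structure_id: str) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for atom in res:
                if atom.name not in groups:
                    groups[atom.name] = []
                    order.append(atom.name)
                groups[atom.name].append(atom)
            atoms = []
            for name in order:
                a = _pick_altloc(groups[name])
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        element=a.element.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    )
                )
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(chain.name, res.seqid.num, icode, res.name, atoms)
            )
    return Structure(structure_id, residues)


def read_pdb(path: str | Path) -> Structure:
    """Read a single-model PDB file.

    Alternate locations are collapsed to one conformer per atom (highest
    occupancy, ties -> altloc 'A'); hydrogens are retained and can be
    identified via :attr:`AtomRecord.is_hydrogen`. Record order is preserved.
    """
    path = Path(path)
    text = path.read_text()
    n_records = _validate_pdb_lines(text, str(path))
    if n_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    st = gemmi.read_pdb_string(text)
    return _model_to_structure(st[0], path.stem)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write ATOM records (fixed-width PDB); round-trips with read_pdb to 3 dp."""
    if s.atom_count() == 0:
        raise EmptyInputError("cannot write a structure with no atoms")
    coords = s.coordinates()
    if np.any(np.abs(coords) >= 9999.999) or np.any(coords <= -999.999):
        raise ValueError("coordinate out of PDB fixed-width range")
    Path(path).write_text(_structure_to_pdb_text(s))


def _structure_to_pdb_text(s: Structure, model_num: int | None = None) -> str:
    buf = io.StringIO()
    if model_num is not None:
        buf.write(f"MODEL     {model_num:4d}\n")
    serial = 1
    last_chain = None
    for r in s.residues:
        if last_chain is not None and r.chain_id != last_chain:
            buf.write("TER\n")
        last_chain = r.chain_id
        for a in r.atoms:
            name = a.atom_name
            # PDB name field: element-aligned for short names
            fname = f" {name:<3s}" if len(name) < 4 and len(a.element) == 1 else f"{name:<4s}"
            x, y, z = a.position
            buf.write(
                f"ATOM  {serial:5d} {fname}{'':1s}{r.res_name:<3s} "
                f"{r.chain_id:1s}{r.res_seq:4d}{r.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element:>2s}\n"
            )
            serial += 1
    buf.write("TER\n")
    buf.write("ENDMDL\n" if model_num is not None else "END\n")
    return buf.getvalue()


def write_frames(fs: FrameSeries, path: str | Path) -> None:
    """Write a FrameSeries as a multi-model PDB."""
    parts = []
    for i in range(len(fs)):
        parts.append(_structure_to_pdb_text(fs.frame_structure(i), model_num=i + 1))
    Path(path).write_text("".join(parts) + "END\n")


def read_frames(
    source: str | Path | Sequence[str | Path],
    frame_interval_ns: float = 1.0,
) -> FrameSeries:
    """Read a frame series from a multi-model PDB or a list of PDB files.

    Model ``i`` (1-based) is assigned time ``i * frame_interval_ns`` — model 1
    is the first sampled nanosecond at the default 1 ns interval. All models
    must share atom count and order.
    """
    structures: list[Structure] = []
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if _validate_pdb_lines(text, str(path)) == 0:
            raise EmptyInputError(f"{path}: no ATOM/HETATM records")
        st = gemmi.read_pdb_string(text)
        for model in st:
            structures.append(_model_to_structure(model, f"{path.stem}"))
    else:
        for p in source:
            structures.append(read_pdb(p))
    if not structures:
        raise EmptyInputError("no models found")
    topo = structures[0]
    n_atoms = topo.atom_count()
    frames = np.empty((len(structures), n_atoms, 3))
    for i, s in enumerate(structures):
        if s.atom_count() != n_atoms:
            raise TopologyMismatchError(
                f"model {i + 1} has {s.atom_count()} atoms, expected {n_atoms}"
            )
        frames[i] = s.coordinates()
    times = frame_interval_ns * np.arange(1, len(structures) + 1)
    return FrameSeries(topology=topo, frames=frames, times=times)


# ---------------------------------------------------------------------------
# Generic numbering and TM segments
# ---------------------------------------------------------------------------

class GenericNumberMap:
    """Ballesteros-Weinstein label -> (chain_id, res_seq) lookup table.

    Labels are generic positions like ``"3.36"`` or ``"6.48"`` plus loop/tail
    aliases such as ``"N-term"`` and ``"ECL2"``.
    """

    def __init__(self, entries: Mapping[str, tuple[str, int]]):
        self.entries: dict[str, tuple[str, int]] = dict(entries)
        if len(self.entries) != len(entries):
            raise ValueError("duplicate labels in generic-number map")

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def lookup(self, label: str) -> tuple[str, int]:
        try:
            return self.entries[label]
        except KeyError:
            raise LookupError_(f"unknown generic label {label!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenericNumberMap":
        df = pd.read_csv(path, sep="\t", dtype={"label": str, "chain": str})
        missing = {"label", "chain", "resseq"} - set(df.columns)
        if missing:
            raise GpcrStateError(f"{path}: missing columns {sorted(missing)}")
        return cls({row.label: (row.chain, int(row.resseq)) for row in df.itertuples()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(lab, c, n) for lab, (c, n) in self.entries.items()],
            columns=["label", "chain", "resseq"],
        ).to_csv(path, sep="\t", index=False)


_TM_NAMES = tuple(f"TM{i}" for i in range(1, 8))


class TMSegmentTable:
    """TM1..TM7 -> (chain_id, first_resseq, last_resseq), inclusive ranges."""

    def __init__(self, segments: Mapping[str, tuple[str, int, int]]):
        if set(segments) != set(_TM_NAMES):
            raise ValueError(f"expected exactly segments {_TM_NAMES}, got {sorted(segments)}")
        self.segments: dict[str, tuple[str, int, int]] = {
            name: segments[name] for name in _TM_NAMES
        }
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for name, (chain, lo, hi) in self.segments.items():
            if hi - lo + 1 < 4:
                raise ValueError(f"{name}: range must contain >= 4 residues")
            spans.setdefault(chain, []).append((lo, hi, name))
        for chain, ranges in spans.items():
            ranges.sort()
            for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
                if lo2 <= hi1:
                    raise ValueError(f"overlapping segments {n1} and {n2} on chain {chain}")

    def __getitem__(self, name: str) -> tuple[str, int, int]:
        return self.segments[name]

    def names(self) -> tuple[str, ...]:
        return _TM_NAMES

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TMSegmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"segment": str, "chain": str})
        missing = {"segment", "chain", "start", "end"} - set(df.columns)
        if missing:
            raise GpcrStateError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            {row.segment: (row.chain, int(row.start), int(row.end)) for row in df.itertuples()}
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(name, c, lo, hi) for name, (c, lo, hi) in self.segments.items()],
            columns=["segment", "chain", "start", "end"],
        ).to_csv(path, sep="\t", index=False)


def resolve_label(s: Structure, m: GenericNumberMap, label: str) -> Residue:
    """Resolve a generic label to the unique residue of ``s`` it names."""
    chain, resseq = m.lookup(label)
    if not s.has_residue(chain, resseq):
        raise LookupError_(
            f"label {label!r} maps to ({chain!r}, {resseq}) which is absent "
            f"from structure {s.id!r}"
        )
    return s.get_residue(chain, resseq)
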