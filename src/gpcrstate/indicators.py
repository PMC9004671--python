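"""Named activation-state indicators and RMSD traces.

Six inter-residue distances summarize where a class A receptor sits between
its inactive and active conformations, each defined on Ballesteros-Weinstein
generic positions:

========== ===============================================================
Y5.58-Y7.53  tyrosine hydroxyl (OH) to tyrosine hydroxyl; TM7 distortion
TM3-TM6      3.50 to 6.34 C-alpha; cytoplasmic opening for G protein
TM2-TM1      2.61 side-chain CZ to 1.36 backbone O; orthosteric pocket
TM2-TM7      2.61 side-chain CZ to 7.36 backbone O; orthosteric pocket
NT-F3.25     N-terminal Phe ring center to 3.25 ring center; N-term insertion
NT-ECL2      N-terminal Phe ring center to ECL2 Phe ring center
========== ===============================================================

Reference values (where published for CB1) are attached to the specs so
per-frame values can be called active-like / inactive-like / intermediate.
The N-terminal probe residue is frequently unmodelled in active structures;
those specs are optional and evaluate to NaN rather than erroring when the
probe is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, LookupError_
from .geometry import (
    BENZENE_RING_ATOMS,
    atom_distance,
    pair_ca_atoms,
    ring_centroid,
    superpose,
)
from .structure_model import (
    FrameSeries,
    GenericNumberMap,
    Structure,
    resolve_label,
)

__all__ = [
    "Endpoint",
    "IndicatorSpec",
    "IndicatorSeries",
    "StateCall",
    "builtin_cb1_indicator_set",
    "evaluate_indicator",
    "indicator_series",
    "call_state",
    "toggle_ca_displacement",
    "overall_rmsd_trace",
    "series_to_tsv",
]

# PDB atom names for names that appear under other spellings in the
# literature (eta-oxygen of tyrosine etc.)
ATOM_ALIASES = {"OETA": "OH", "OH(ETA)": "OH"}


@dataclass(frozen=True)
class Endpoint:
    """One end of an indicator: a generic label plus how to turn it into a point.

    mode "atom" uses the named atom; mode "ring" uses the benzene-ring
    centroid.
    """

    label: str
    mode: str = "atom"  # "atom" | "ring"
    atom_name: str | None = None
    ring_atoms: tuple[str, ...] = BENZENE_RING_ATOMS

    def resolve(self, s: Structure, gmap: GenericNumberMap) -> np.ndarray:
        res = resolve_label(s, gmap, self.label)
        if self.mode == "ring":
            return ring_centroid(res, self.ring_atoms)
        name = ATOM_ALIASES.get((self.atom_name or "").upper(), self.atom_name)
        if name is None:
            raise ConfigError(f"endpoint {self.label!r} in atom mode needs atom_name")
        if not res.has_atom(name):
            from .errors import IncompleteSideChainError

            raise IncompleteSideChainError(
                f"residue for label {self.label!r} has no atom {name!r}"
            )
        return res.atom(name).position


@dataclass(frozen=True)
class IndicatorSpec:
    name: str
    endpoint_a: Endpoint
    endpoint_b: Endpoint
    reference_inactive: float | None = None
    reference_active: float | None = None
    optional_labels: tuple[str, ...] = ()  # endpoints allowed to be unmodelled

    def __post_init__(self) -> None:
        for ref in (self.reference_inactive, self.reference_active):
            if ref is not None and ref <= 0:
                raise ValueError(f"{self.name}: reference distances must be positive")


@dataclass
class IndicatorSeries:
    spec_name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values lengths differ")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("indicator values must be nonnegative")


@dataclass
class StateCall:
    """Per-frame categorical call against the spec's two reference values."""

    spec_name: str
    labels: list[str]  # active-like | inactive-like | intermediate


def builtin_cb1_indicator_set() -> list[IndicatorSpec]:
    """The six CB1 indicators with published reference distances attached.

    Y5.58-Y7.53: 10.5 A inactive / 3.4 A active; TM3-TM6: 8.2 / 13.8 A.
    The two N-terminal indicators carry no active reference (the probe
    residue is not modelled in the active reference structure).
    """
    return [
        IndicatorSpec(
            "Y5.58-Y7.53",
            Endpoint("5.58", "atom", "OH"),
            Endpoint("7.53", "atom", "OH"),
            reference_inactive=10.5,
            reference_active=3.4,
        ),
        IndicatorSpec(
            "TM3-TM6",
            Endpoint("3.50", "atom", "CA"),
            Endpoint("6.34", "atom", "CA"),
            reference_inactive=8.2,
            reference_active=13.8,
        ),
        IndicatorSpec(
            "TM2-TM1",
            Endpoint("2.61", "atom", "CZ"),
            Endpoint("1.36", "atom", "O"),
        ),
        IndicatorSpec(
            "TM2-TM7",
            Endpoint("2.61", "atom", "CZ"),
            Endpoint("7.36", "atom", "O"),
        ),
        IndicatorSpec(
            "NT-F3.25",
            Endpoint("N-term", "ring"),
            Endpoint("3.25", "ring"),
            optional_labels=("N-term",),
        ),
        IndicatorSpec(
            "NT-ECL2",
            Endpoint("N-term", "ring"),
            Endpoint("ECL2", "ring"),
            optional_labels=("N-term",),
        ),
    ]


def evaluate_indicator(s: Structure, spec: IndicatorSpec, gmap: GenericNumberMap) -> float:
    """Distance in A between the spec's two endpoints on one structure.

    Returns NaN if an endpoint listed in ``optional_labels`` is absent from
    the structure (unmodelled probe residue); other resolution failures
    raise.
    """
    points = []
    for ep in (spec.endpoint_a, spec.endpoint_b):
        try:
            points.append(ep.resolve(s, gmap))
        except LookupError_:
            if ep.label in spec.optional_labels:
                return math.nan
            raise
    return atom_distance(points[0], points[1])


def indicator_series(
    fs: FrameSeries, specs: list[IndicatorSpec], gmap: GenericNumberMap
) -> list[IndicatorSeries]:
    """Evaluate each spec on every frame; one series per spec."""
    out = []
    values = np.empty((len(specs), len(fs)))
    for i in range(len(fs)):
        frame = fs.frame_structure(i)
        for j, spec in enumerate(specs):
            try:
                values[j, i] = evaluate_indicator(frame, spec, gmap)
            except Exception as e:
                raise type(e)(f"frame {i}: {e}") from e
    for j, spec in enumerate(specs):
        out.append(IndicatorSeries(spec.name, fs.times.copy(), values[j]))
    return out


def call_state(series: IndicatorSeries, spec: IndicatorSpec, tolerance: float = 1.0) -> StateCall:
    """Call each frame active-like / inactive-like / intermediate.

    A frame matches a reference when within ``tolerance`` A of it; when both
    references match, the nearer one wins and an exact tie is intermediate.
    """
    if spec.reference_active is None or spec.reference_inactive is None:
        raise ConfigError(f"{spec.name}: both references required for state calls")
    labels = []
    for v in series.values:
        da = abs(v - spec.reference_active)
        di = abs(v - spec.reference_inactive)
        hit_a, hit_i = da <= tolerance, di <= tolerance
        if hit_a and hit_i:
            labels.append(
                "active-like" if da < di else "inactive-like" if di < da else "intermediate"
            )
        elif hit_a:
            labels.append("active-like")
        elif hit_i:
            labels.append("inactive-like")
        else:
            labels.append("intermediate")
    return StateCall(series.spec_name, labels)


def toggle_ca_displacement(
    inactive: Structure,
    active: Structure,
    gmap: GenericNumberMap,
    tm3_range: tuple[str, int, int],
) -> float:
    """Displacement of the 6.48 C-alpha between two structures, TM3 aligned.

    The active structure is superposed onto the inactive one using TM3
    C-alpha atoms; the returned value is the distance between the two 6.48
    C-alpha positions after that alignment.
    """
    pa, pb = pair_ca_atoms(inactive, active, [tm3_range], strict=True)
    transform, _ = superpose(pb, pa)  # active onto inactive
    ca_inact = resolve_label(inactive, gmap, "6.48").atom("CA").position
    ca_act = resolve_label(active, gmap, "6.48").atom("CA").position
    return atom_distance(ca_inact, transform.apply(ca_act[None, :])[0])


def overall_rmsd_trace(
    fs: FrameSeries,
    reference: Structure,
    ranges: list[tuple[str, int, int]],
) -> IndicatorSeries:
    """Per-frame minimized C-alpha RMSD to a reference over residue ranges."""
    values = np.empty(len(fs))
    for i in range(len(fs)):
        frame = fs.frame_structure(i)
        pa, pb = pair_ca_atoms(reference, frame, ranges, strict=True)
        _, values[i] = superpose(pb, pa)
    return IndicatorSeries(f"RMSD-to-{reference.id}", fs.times.copy(), values)


def series_to_tsv(series: list[IndicatorSeries], path) -> None:
    """Long-format TSV: time_ns, indicator, value_A."""
    rows = [
        (t, s.spec_name, v)
        for s in series
        for t, v in zip(s.times, s.values)
    ]
    pd.DataFrame(rows, columns=["time_ns", "indicator", "value_A"]).to_csv(
        path, sep="\t", index=False
    )
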