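"""Per-frame classification of the 3.36/6.48 twin-toggle-switch configuration.

The twin toggle switch is the paired rotamer/position exchange of the 3.36
and 6.48 side chains (Phe and Trp in CB1). Each frame is reduced to a
:class:`ToggleObservation` — the 3.36 chi1 and 6.48 chi2 dihedrals, whether
the two ring centroids sit in swapped order along the bundle axis relative
to the inactive reference, and how far the 6.48 C-alpha has slid from its
active-state position (TM3 aligned) — and classified against a
:class:`CentroidTable` of rotamer-well centers on the (chi1, chi2) torus:

* ``active`` — dihedrals in the active well;
* ``inactive`` — dihedrals in the inactive well, positions not swapped;
* ``reversed_inactive`` — inactive dihedrals but the residues still occupy
  their active (swapped) positions;
* ``pushed`` — the 6.48 chi2 in a novel rotamer well, displaced by the
  3.36 side chain;
* ``sliding`` — active-like chi1 with shifted chi2 while the 6.48 backbone
  has slid toward the inactive position;
* ``unassigned`` — anything else.

The torus metric is the maximum of the two wrapped angle differences, so
each well is a square window in (chi1, chi2). Centroids default to values
measured from the reference structures at table construction; the novel
(pushed) chi2 well defaults to the inactive 6.48 rotamer displaced by +120
degrees.

The pooled ``active_ratio`` over one or more runs is the headline statistic:
near 1 under full agonists, near 0.85 for partial agonist / neutral
antagonist / apo regimes, 0 under inverse agonists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, MutantDetectedError, NoChiAngleError
from .geometry import (
    angle_difference,
    atom_distance,
    chi_angles,
    pair_ca_atoms,
    ring_centroid,
    superpose,
    wrap_angle,
)
from .structure_model import GenericNumberMap, Structure, resolve_label

__all__ = [
    "TOGGLE_LABELS",
    "ToggleObservation",
    "CentroidTable",
    "observe_toggle",
    "classify",
    "active_ratio",
    "dwell_segments",
    "TRP_SIX_RING_ATOMS",
]

TOGGLE_LABELS = ("active", "inactive", "reversed_inactive", "pushed", "sliding", "unassigned")

#: Six-membered (benzene) ring of the tryptophan indole.
TRP_SIX_RING_ATOMS = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")


@dataclass(frozen=True)
class ToggleObservation:
    """Geometric features of the toggle pair in one frame."""

    chi1_336: float
    chi2_648: float
    pos_reversed: bool
    ca_slide_648: float  # A, displacement of 6.48 CA from its active position

    def __post_init__(self) -> None:
        if not (-180.0 < self.chi1_336 <= 180.0 and -180.0 < self.chi2_648 <= 180.0):
            raise ValueError("chi angles must be wrapped into (-180, 180]")
        if self.ca_slide_648 < 0:
            raise ValueError("ca_slide_648 must be >= 0")


@dataclass
class CentroidTable:
    """Rotamer-well centers, the square angular window, and slide threshold."""

    centroids: dict[str, tuple[float, float]]  # label -> (chi1, chi2) deg
    window_deg: float = 40.0
    slide_threshold: float = 2.0  # A

    def __post_init__(self) -> None:
        if self.window_deg <= 0:
            raise ValueError("window must be positive")
        for label in ("active", "inactive", "pushed"):
            if label not in self.centroids:
                raise ConfigError(f"centroid table missing label {label!r}")

    @classmethod
    def from_references(
        cls,
        active: Structure,
        inactive: Structure,
        gmap: GenericNumberMap,
        window_deg: float = 40.0,
        slide_threshold: float = 2.0,
        pushed_chi2_offset: float = 120.0,
    ) -> "CentroidTable":
        """Measure well centers from the two reference structures.

        The active and inactive wells take their (3.36 chi1, 6.48 chi2)
        straight from the references; the pushed well reuses the inactive
        chi1 with chi2 displaced by ``pushed_chi2_offset``.
        """
        chi_a = _toggle_chis(active, gmap)
        chi_i = _toggle_chis(inactive, gmap)
        return cls(
            centroids={
                "active": chi_a,
                "inactive": chi_i,
                "pushed": (chi_i[0], wrap_angle(chi_i[1] + pushed_chi2_offset)),
            },
            window_deg=window_deg,
            slide_threshold=slide_threshold,
        )


def _toggle_chis(s: Structure, gmap: GenericNumberMap) -> tuple[float, float]:
    try:
        chi1_336, _ = chi_angles(resolve_label(s, gmap, "3.36"))
        _, chi2_648 = chi_angles(resolve_label(s, gmap, "6.48"))
    except NoChiAngleError as e:
        raise MutantDetectedError(
            f"toggle position carries a side chain without chi angles: {e}"
        ) from e
    if chi2_648 is None:
        raise MutantDetectedError("6.48 residue has no chi2")
    return chi1_336, chi2_648


def _ring_atoms_for(res_name: str) -> tuple[str, ...]:
    from .geometry import BENZENE_RING_ATOMS

    return TRP_SIX_RING_ATOMS if res_name.upper() == "TRP" else BENZENE_RING_ATOMS


def _bundle_axis(s: Structure) -> np.ndarray:
    """Principal axis of the C-alpha cloud (unit vector, +z hemisphere)."""
    cas = np.array([r.atom("CA").position for r in s if r.has_atom("CA")])
    cas = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas, full_matrices=False)
    axis = vt[0]
    return axis if axis[2] >= 0 else -axis


def observe_toggle(
    frame: Structure,
    gmap: GenericNumberMap,
    inactive_ref: Structure,
    tm3_range: tuple[str, int, int],
    active_ref: Structure,
) -> ToggleObservation:
    """Measure the toggle features of one frame.

    The frame is superposed onto the inactive reference on TM3 C-alpha
    atoms. ``pos_reversed`` compares the order of the 3.36/6.48 ring
    centroids along the inactive reference's bundle axis; ``ca_slide_648``
    is the distance of the frame's 6.48 C-alpha from its active-reference
    position in the same TM3-aligned frame (how far the backbone has slid
    away from the active state).
    """
    chi1_336, chi2_648 = _toggle_chis(frame, gmap)

    ri, rf = pair_ca_atoms(inactive_ref, frame, [tm3_range], strict=True)
    t_frame, _ = superpose(rf, ri)
    ri2, ra = pair_ca_atoms(inactive_ref, active_ref, [tm3_range], strict=True)
    t_active, _ = superpose(ra, ri2)

    def centroid(s: Structure, transform) -> dict[str, np.ndarray]:
        out = {}
        for label in ("3.36", "6.48"):
            res = resolve_label(s, gmap, label)
            c = ring_centroid(res, _ring_atoms_for(res.res_name))
            out[label] = transform.apply(c[None, :])[0] if transform is not None else c
        return out

    c_ref = centroid(inactive_ref, None)
    c_frm = centroid(frame, t_frame)
    axis = _bundle_axis(inactive_ref)
    s_ref = float(np.dot(c_ref["6.48"] - c_ref["3.36"], axis))
    s_frm = float(np.dot(c_frm["6.48"] - c_frm["3.36"], axis))
    pos_reversed = (s_frm * s_ref) < 0

    ca_frame = t_frame.apply(
        resolve_label(frame, gmap, "6.48").atom("CA").position[None, :]
    )[0]
    ca_active = t_active.apply(
        resolve_label(active_ref, gmap, "6.48").atom("CA").position[None, :]
    )[0]
    slide = atom_distance(ca_frame, ca_active)

    return ToggleObservation(chi1_336, chi2_648, pos_reversed, slide)


def classify(obs: ToggleObservation, table: CentroidTable) -> str:
    """Deterministic, total decision rule over the observation.

    1. nearest centroid on the torus (L-infinity) within the window wins;
       a dihedral match to the inactive well splits on ``pos_reversed``
       into inactive vs reversed_inactive;
    2. otherwise active-like chi1 with shifted chi2 and a backbone slide
       beyond threshold is sliding;
    3. otherwise a chi2 in the novel (pushed) well is pushed;
    4. otherwise unassigned.
    """

    def torus_dist(c: tuple[float, float]) -> float:
        return max(
            angle_difference(obs.chi1_336, c[0]),
            angle_difference(obs.chi2_648, c[1]),
        )

    dists = {label: torus_dist(c) for label, c in table.centroids.items()}
    within = {l: d for l, d in dists.items() if d <= table.window_deg}
    if within:
        # nearest centroid; ties resolved by fixed label order
        order = ("active", "inactive", "pushed")
        label = min(within, key=lambda l: (within[l], order.index(l) if l in order else 99))
        if label == "inactive":
            return "reversed_inactive" if obs.pos_reversed else "inactive"
        return label

    chi1_active_like = (
        angle_difference(obs.chi1_336, table.centroids["active"][0]) <= table.window_deg
    )
    if chi1_active_like and obs.ca_slide_648 > table.slide_threshold:
        return "sliding"
    if angle_difference(obs.chi2_648, table.centroids["pushed"][1]) <= table.window_deg:
        return "pushed"
    return "unassigned"


def active_ratio(
    labels: Sequence[str] | Iterable[Sequence[str]],
    per_run_average: bool = False,
) -> float:
    """Fraction of frames in the ``active`` configuration.

    Accepts one run (sequence of labels) or several; by default runs are
    pooled by frame count. ``per_run_average`` instead averages each run's
    own ratio.
    """
    runs: list[list[str]]
    seq = list(labels)
    if not seq:
        raise ValueError("active_ratio needs at least one label")
    if isinstance(seq[0], str):
        runs = [seq]  # type: ignore[list-item]
    else:
        runs = [list(r) for r in seq]
        if any(len(r) == 0 for r in runs) or not runs:
            raise ValueError("active_ratio needs at least one label per run")
    for run in runs:
        for l in run:
            if l not in TOGGLE_LABELS:
                raise ValueError(f"unknown toggle label {l!r}")
    if per_run_average:
        return float(np.mean([run.count("active") / len(run) for run in runs]))
    total = sum(len(run) for run in runs)
    return sum(run.count("active") for run in runs) / total


def dwell_segments(
    labels: Sequence[str], times: Sequence[float]
) -> list[tuple[str, float, float]]:
    """Maximal constant-label runs as (label, start_ns, end_ns)."""
    if len(labels) != len(times):
        raise ValueError("labels and times lengths differ")
    if not labels:
        return []
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append((labels[start], float(times[start]), float(times[i - 1])))
            start = i
    return segments
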