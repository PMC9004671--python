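"""Residue-residue contact score (RRCS), state differences, and ranking.

RRCS quantifies the strength of contact between two residues as a sum over
their heavy-atom pairs of a piecewise-linear function of distance d:

    1                                if d <= d_full
    (d_zero - d) / (d_zero - d_full) if d_full < d < d_zero
    0                                if d >= d_zero

with defaults d_full = 3.23 A and d_zero = 4.63 A. For residue pairs close
in sequence on the same chain (|separation| <= 4 by default) the backbone
atoms N, CA, C, O are excluded so the score reflects side-chain packing.

|dRRCS| — the absolute difference of a pair's RRCS between the inactive and
active structure of a receptor — measures how much that contact is remodeled
by activation; ranking receptors by the 3.36/6.48 |dRRCS| singles out those
with a twin-toggle-switch mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_model import GenericNumberMap, Residue, Structure, resolve_label

__all__ = [
    "RRCSParams",
    "RRCSResult",
    "DeltaRRCS",
    "rrcs_pair",
    "delta_rrcs",
    "rank_receptors",
    "ranking_to_tsv",
]


@dataclass(frozen=True)
class RRCSParams:
    d_full: float = 3.23  # A; score saturates at 1 per atom pair below this
    d_zero: float = 4.63  # A; score reaches 0 at or beyond this
    near_seq_sep: int = 4  # same-chain sequence separation for backbone exclusion
    excluded_backbone_atoms: frozenset[str] = frozenset({"N", "CA", "C", "O"})

    def __post_init__(self) -> None:
        if not (0 < self.d_full < self.d_zero):
            raise ValueError("require 0 < d_full < d_zero")
        if self.near_seq_sep < 0:
            raise ValueError("near_seq_sep must be >= 0")


@dataclass(frozen=True)
class RRCSResult:
    pair: tuple[str, str]
    score: float


@dataclass(frozen=True)
class DeltaRRCS:
    receptor_id: str
    pair: tuple[str, str]
    value: float  # |score_inactive - score_active|
    score_inactive: float = 0.0
    score_active: float = 0.0


def _qualifying_atoms(res: Residue, other: Residue, params: RRCSParams) -> np.ndarray:
    """Heavy-atom coordinates of ``res`` that participate in scoring."""
    near = (
        res.chain_id == other.chain_id
        and abs(res.res_seq - other.res_seq) <= params.near_seq_sep
    )
    atoms = [
        a
        for a in res.heavy_atoms()
        if not (near and a.atom_name in params.excluded_backbone_atoms)
    ]
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.position for a in atoms])


def rrcs_pair(
    s: Structure, res_a: Residue, res_b: Residue, params: RRCSParams | None = None
) -> RRCSResult:
    """Contact score between two residues of a structure (symmetric).

    ``s`` provides context only; the residues themselves carry the atoms.
    """
    if params is None:
        params = RRCSParams()
    if res_a.key() == res_b.key():
        raise ValueError("RRCS requires two distinct residues")
    pa = _qualifying_atoms(res_a, res_b, params)
    pb = _qualifying_atoms(res_b, res_a, params)
    if len(pa) == 0 or len(pb) == 0:
        score = 0.0
    else:
        d = cdist(pa, pb)
        contrib = np.clip((params.d_zero - d) / (params.d_zero - params.d_full), 0.0, 1.0)
        score = float(contrib.sum())
    label_a = f"{res_a.chain_id}:{res_a.res_name}{res_a.res_seq}"
    label_b = f"{res_b.chain_id}:{res_b.res_name}{res_b.res_seq}"
    return RRCSResult(pair=(label_a, label_b), score=score)


def delta_rrcs(
    inactive: Structure,
    active: Structure,
    pair_labels: tuple[str, str] = ("3.36", "6.48"),
    gmap_inactive: GenericNumberMap | None = None,
    gmap_active: GenericNumberMap | None = None,
    params: RRCSParams | None = None,
    receptor_id: str = "",
) -> DeltaRRCS:
    """|RRCS_inactive - RRCS_active| for a labeled residue pair."""
    if gmap_inactive is None:
        raise ValueError("a generic-number map is required")
    gmap_active = gmap_active or gmap_inactive
    la, lb = pair_labels
    score_i = rrcs_pair(
        inactive,
        resolve_label(inactive, gmap_inactive, la),
        resolve_label(inactive, gmap_inactive, lb),
        params,
    ).score
    score_a = rrcs_pair(
        active,
        resolve_label(active, gmap_active, la),
        resolve_label(active, gmap_active, lb),
        params,
    ).score
    return DeltaRRCS(
        receptor_id=receptor_id or inactive.id,
        pair=pair_labels,
        value=abs(score_i - score_a),
        score_inactive=score_i,
        score_active=score_a,
    )


def rank_receptors(
    entries: list[tuple[str, Structure, Structure, GenericNumberMap]],
    pair_labels: tuple[str, str] = ("3.36", "6.48"),
    params: RRCSParams | None = None,
) -> list[DeltaRRCS]:
    """Rank receptors by descending |dRRCS| of the labeled pair.

    Each entry is (receptor id, inactive structure, active structure, map).
    Ties are broken by receptor id, lexicographically.
    """
    if not entries:
        raise ValueError("rank_receptors needs at least one entry")
    results = [
        delta_rrcs(
            inact, act, pair_labels, gmap_inactive=gmap, params=params, receptor_id=rid
        )
        for rid, inact, act, gmap in entries
    ]
    return sorted(results, key=lambda r: (-r.value, r.receptor_id))


def ranking_to_tsv(results: list[DeltaRRCS], path, params: RRCSParams | None = None) -> None:
    params = params or RRCSParams()
    df = pd.DataFrame(
        [
            (r.receptor_id, f"{r.pair[0]}/{r.pair[1]}", r.score_inactive, r.score_active,
             r.value, rank + 1)
            for rank, r in enumerate(results)
        ],
        columns=["receptor", "pair", "rrcs_inactive", "rrcs_active", "abs_delta", "rank"],
    )
    with open(path, "w") as fh:
        fh.write(
            f"# RRCS params: d_full={params.d_full} d_zero={params.d_zero} "
            f"near_seq_sep={params.near_seq_sep} "
            f"excluded={sorted(params.excluded_backbone_atoms)}\n"
        )
        df.to_csv(fh, sep="\t", index=False)
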