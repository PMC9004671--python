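"""P-I-F motif conservation counting at generic positions 5.50/3.40/6.44.

The P5.50-I3.40-F6.44 connector motif is a well-known class A activation
microswitch, but it is not universal; receptors are scored by how many of
the three consensus residues they retain (0-3). CB1, for instance, carries
L/V/L at the three positions and scores 0. Input is a table of one-letter
codes per receptor; deriving those codes from any particular database
snapshot is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

__all__ = ["MotifCall", "pif_call", "pif_census", "scan_tsv", "census_to_json"]

_POSITIONS = ("5.50", "3.40", "6.44")
_CONSENSUS = {"5.50": "P", "3.40": "I", "6.44": "F"}


@dataclass(frozen=True)
class MotifCall:
    receptor_id: str
    residues: dict[str, str]  # position -> one-letter code ("-" for gap)
    conserved_count: int


def pif_call(residues_at_positions: dict[str, str], receptor_id: str = "") -> MotifCall:
    """Count positions matching the P/I/F consensus; gaps never match."""
    missing = [p for p in _POSITIONS if p not in residues_at_positions]
    if missing:
        raise ValueError(f"missing positions: {missing}")
    codes = {p: residues_at_positions[p].strip().upper() for p in _POSITIONS}
    count = sum(1 for p in _POSITIONS if codes[p] == _CONSENSUS[p])
    return MotifCall(receptor_id=receptor_id, residues=codes, conserved_count=count)


def pif_census(calls: list[MotifCall]) -> dict[int, int]:
    """Histogram over conserved_count 0..3; totals equal the input size."""
    hist = {k: 0 for k in range(4)}
    for c in calls:
        hist[c.conserved_count] += 1
    return hist


def scan_tsv(path) -> list[MotifCall]:
    """Read (receptor, res5x50, res3x40, res6x44) rows and call each."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"receptor", "res5x50", "res3x40", "res6x44"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        pif_call(
            {"5.50": row.res5x50, "3.40": row.res3x40, "6.44": row.res6x44},
            receptor_id=row.receptor,
        )
        for row in df.itertuples()
    ]


def census_to_json(calls: list[MotifCall], path) -> None:
    hist = pif_census(calls)
    with open(path, "w") as fh:
        json.dump(
            {
                "histogram": {str(k): v for k, v in hist.items()},
                "receptors": {c.receptor_id: c.conserved_count for c in calls},
            },
            fh,
            indent=2,
        )
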