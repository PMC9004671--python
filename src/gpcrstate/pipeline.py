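"""End-to-end orchestration: config validation, stage execution, reporting.

A run configuration names input files (structures, frames, numbering map,
segment table, motif table), toggles stages on or off, and sets stage
parameters. Stages execute in a fixed order — indicators, toggle
classification, contact score, helix matrix, motif scan — each writing its
own TSV/JSON artifact into the output directory, plus a provenance block
(config echo, package version, seed). Validation collects every problem
before aborting so a bad config fails in one pass; no partial outputs are
written on validation failure.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .contact_score import RRCSParams, delta_rrcs, ranking_to_tsv, rank_receptors
from .errors import ConfigError
from .helix_matrix import matrix_to_tsv, movement_profile, rmsd_matrix_7x7
from .indicators import (
    builtin_cb1_indicator_set,
    call_state,
    indicator_series,
    series_to_tsv,
)
from .motif_scan import census_to_json, scan_tsv
from .structure_model import (
    GenericNumberMap,
    TMSegmentTable,
    read_frames,
    read_pdb,
)
from .toggle_classifier import (
    CentroidTable,
    active_ratio,
    classify,
    dwell_segments,
    observe_toggle,
)

__all__ = ["RunConfig", "Report", "run_pipeline", "load_config"]

log = logging.getLogger("gpcrstate")

_STAGE_ORDER = ("indicators", "toggle", "rrcs", "matrix77", "motif")

_STAGE_INPUTS = {
    "indicators": ("frames", "map"),
    "toggle": ("frames", "map", "inactive", "active", "segments"),
    "rrcs": ("inactive", "active", "map"),
    "matrix77": ("inactive", "active", "segments"),
    "motif": ("motif_table",),
}


@dataclass
class RunConfig:
    inputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "gpcrstate-out"

    def enabled_stages(self) -> list[str]:
        return [s for s in _STAGE_ORDER if self.stages.get(s, False)]

    def validate(self) -> None:
        problems: list[str] = []
        enabled = self.enabled_stages()
        if not enabled:
            problems.append("no stages enabled")
        for stage in enabled:
            for key in _STAGE_INPUTS[stage]:
                path = self.inputs.get(key)
                if not path:
                    problems.append(f"stage {stage!r} needs input {key!r}")
                elif not Path(path).exists():
                    problems.append(f"input {key!r}: file not found: {path}")
        for stage in self.stages:
            if stage not in _STAGE_ORDER:
                problems.append(f"unknown stage {stage!r}")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class Report:
    artifacts: dict[str, str]
    provenance: dict[str, Any]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        inputs=raw.get("inputs", {}),
        stages=raw.get("stages", {}),
        params=raw.get("params", {}),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "gpcrstate-out"),
    )


def run_pipeline(cfg: RunConfig) -> Report:
    """Validate, run enabled stages in order, and write artifacts."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    ctx: dict[str, Any] = {}

    def get_map() -> GenericNumberMap:
        if "map" not in ctx:
            ctx["map"] = GenericNumberMap.from_tsv(cfg.inputs["map"])
        return ctx["map"]

    def get_segments() -> TMSegmentTable:
        if "segments" not in ctx:
            ctx["segments"] = TMSegmentTable.from_tsv(cfg.inputs["segments"])
        return ctx["segments"]

    def get_frames():
        if "frames" not in ctx:
            interval = float(cfg.params.get("frame_interval_ns", 1.0))
            ctx["frames"] = read_frames(cfg.inputs["frames"], frame_interval_ns=interval)
        return ctx["frames"]

    for stage in cfg.enabled_stages():
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)

        if stage == "indicators":
            fs = get_frames()
            specs = builtin_cb1_indicator_set()
            series = indicator_series(fs, specs, get_map())
            path = outdir / "indicators.tsv"
            series_to_tsv(series, path)
            artifacts["indicators"] = str(path)
            tol = float(cfg.params.get("state_call_tolerance", 1.0))
            calls = {}
            for s, spec in zip(series, specs):
                if spec.reference_active is not None and spec.reference_inactive is not None:
                    calls[spec.name] = call_state(s, spec, tolerance=tol).labels
            call_path = outdir / "state_calls.json"
            call_path.write_text(json.dumps(calls, indent=2))
            artifacts["state_calls"] = str(call_path)

        elif stage == "toggle":
            fs = get_frames()
            gmap = get_map()
            inactive = read_pdb(cfg.inputs["inactive"])
            active = read_pdb(cfg.inputs["active"])
            tm3 = get_segments()["TM3"]
            table = CentroidTable.from_references(
                active,
                inactive,
                gmap,
                window_deg=float(cfg.params.get("window_deg", 40.0)),
                slide_threshold=float(cfg.params.get("slide_threshold", 2.0)),
            )
            rows = []
            labels = []
            for i in range(len(fs)):
                obs = observe_toggle(fs.frame_structure(i), gmap, inactive, tm3, active)
                label = classify(obs, table)
                labels.append(label)
                rows.append(
                    (fs.times[i], obs.chi1_336, obs.chi2_648, obs.pos_reversed,
                     obs.ca_slide_648, label)
                )
            import pandas as pd

            path = outdir / "toggle.tsv"
            pd.DataFrame(
                rows,
                columns=["time_ns", "chi1_deg", "chi2_deg", "pos_reversed",
                         "ca_slide_A", "label"],
            ).to_csv(path, sep="\t", index=False)
            artifacts["toggle"] = str(path)
            summary = {
                "active_ratio": active_ratio(labels),
                "dwell_segments": dwell_segments(labels, list(fs.times)),
            }
            spath = outdir / "toggle_summary.json"
            spath.write_text(json.dumps(summary, indent=2))
            artifacts["toggle_summary"] = str(spath)

        elif stage == "rrcs":
            inactive = read_pdb(cfg.inputs["inactive"])
            active = read_pdb(cfg.inputs["active"])
            gmap = get_map()
            rp = RRCSParams(**cfg.params.get("rrcs", {}))
            pair = tuple(cfg.params.get("pair_labels", ("3.36", "6.48")))
            result = delta_rrcs(
                inactive, active, pair, gmap_inactive=gmap, params=rp,
                receptor_id=cfg.params.get("receptor_id", "receptor"),
            )
            path = outdir / "rrcs.tsv"
            ranking_to_tsv([result], path, params=rp)
            artifacts["rrcs"] = str(path)

        elif stage == "matrix77":
            inactive = read_pdb(cfg.inputs["inactive"])
            active = read_pdb(cfg.inputs["active"])
            m = rmsd_matrix_7x7(inactive, active, get_segments())
            path = outdir / "matrix77.tsv"
            matrix_to_tsv(m, path)
            artifacts["matrix77"] = str(path)
            thr = float(cfg.params.get("movement_threshold", 2.0))
            count, pairs = movement_profile(m, thr)
            mpath = outdir / "movement.json"
            mpath.write_text(
                json.dumps({"threshold_A": thr, "count": count,
                            "pairs": [list(p) for p in pairs]}, indent=2)
            )
            artifacts["movement"] = str(mpath)

        elif stage == "motif":
            calls = scan_tsv(cfg.inputs["motif_table"])
            path = outdir / "motif.json"
            census_to_json(calls, path)
            artifacts["motif"] = str(path)

        timings[stage] = time.perf_counter() - t0
        log.info("stage %s: done in %.2f s", stage, timings[stage])

    provenance = {
        "package": "gpcrstate",
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            "inputs": cfg.inputs,
            "stages": cfg.stages,
            "params": cfg.params,
            "output_dir": cfg.output_dir,
        },
        "timings_s": timings,
    }
    ppath = outdir / "provenance.json"
    ppath.write_text(json.dumps(provenance, indent=2, default=str))
    artifacts["provenance"] = str(ppath)
    return Report(artifacts=artifacts, provenance=provenance)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
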