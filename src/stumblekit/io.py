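"""Disk layout for trial bundles.

One directory per walking block:

* ``markers.csv`` - time, marker, x, y, z, valid
* ``forces.csv`` - time, plate, fx, fy, fz
* ``belt.csv`` - time, speed
* ``static.csv`` - time, plate, fx, fy, fz (T-pose trial)
* ``meta.json`` - participant mass, stimulation condition, perturbation
  duration, prosthetic side, preferred speed, sampling rates
* ``ground_truth.json`` - optional oracle annotations
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GroundTruth,
    GroundTruthPerturbation,
    SIDES,
    StaticTrial,
    TrialMeta,
    TrialRecording,
)


def save_bundle(directory, trial: TrialRecording, truth: GroundTruth | None = None,
                static: StaticTrial | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tm = trial.marker_time()
    frames = []
    for name, pos in trial.markers.items():
        frames.append(pd.DataFrame({
            "time": tm, "marker": name, "x": pos[:, 0], "y": pos[:, 1],
            "z": pos[:, 2], "valid": trial.marker_valid[name].astype(int)}))
    pd.concat(frames, ignore_index=True).to_csv(directory / "markers.csv",
                                                index=False, float_format="%.6f")
    tf = trial.force_time()
    frames = []
    for side in SIDES:
        f = trial.forces[side]
        frames.append(pd.DataFrame({"time": tf, "plate": side, "fx": f[:, 0],
                                    "fy": f[:, 1], "fz": f[:, 2]}))
    pd.concat(frames, ignore_index=True).to_csv(directory / "forces.csv",
                                                index=False, float_format="%.6f")
    pd.DataFrame({"time": tf, "speed": trial.belt_speed}).to_csv(
        directory / "belt.csv", index=False, float_format="%.6f")
    meta = dataclasses.asdict(trial.meta)
    meta["marker_rate"] = trial.marker_rate
    meta["force_rate"] = trial.force_rate
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    if static is not None:
        ts = np.arange(next(iter(static.forces.values())).shape[0]) / static.rate
        frames = []
        for side in SIDES:
            f = static.forces[side]
            frames.append(pd.DataFrame({"time": ts, "plate": side, "fx": f[:, 0],
                                        "fy": f[:, 1], "fz": f[:, 2]}))
        pd.concat(frames, ignore_index=True).to_csv(
            directory / "static.csv", index=False, float_format="%.6f")
    if truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(_truth_to_dict(truth), indent=1))
    return directory


def load_bundle(directory):
    """Load a trial bundle: (trial, truth-or-None, static-or-None)."""
    directory = Path(directory)
    meta_d = json.loads((directory / "meta.json").read_text())
    marker_rate = float(meta_d.pop("marker_rate"))
    force_rate = float(meta_d.pop("force_rate"))
    meta = TrialMeta(**meta_d)

    mk = pd.read_csv(directory / "markers.csv")
    markers, valid = {}, {}
    for name, sub in mk.groupby("marker", sort=False):
        sub = sub.sort_values("time")
        markers[name] = sub[["x", "y", "z"]].to_numpy(dtype=float)
        valid[name] = sub["valid"].to_numpy(dtype=int).astype(bool)

    fc = pd.read_csv(directory / "forces.csv")
    forces = {}
    n_force = None
    for side, sub in fc.groupby("plate", sort=False):
        sub = sub.sort_values("time")
        forces[side] = sub[["fx", "fy", "fz"]].to_numpy(dtype=float)
        n_force = forces[side].shape[0]
    belt = pd.read_csv(directory / "belt.csv").sort_values("time")
    belt_speed = belt["speed"].to_numpy(dtype=float)[:n_force]

    trial = TrialRecording(markers=markers, marker_valid=valid,
                           marker_rate=marker_rate, forces=forces,
                           force_rate=force_rate, belt_speed=belt_speed, meta=meta)
    static = None
    if (directory / "static.csv").exists():
        sc = pd.read_csv(directory / "static.csv")
        sforces = {side: sub.sort_values("time")[["fx", "fy", "fz"]].to_numpy(dtype=float)
                   for side, sub in sc.groupby("plate", sort=False)}
        static = StaticTrial(forces=sforces, rate=force_rate)
    truth = None
    if (directory / "ground_truth.json").exists():
        truth = _truth_from_dict(
            json.loads((directory / "ground_truth.json").read_text()))
    return trial, truth, static


def _truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "heel_strikes": {s: list(map(float, v)) for s, v in truth.heel_strikes.items()},
        "toe_offs": {s: list(map(float, v)) for s, v in truth.toe_offs.items()},
        "perturbations": [dataclasses.asdict(p) for p in truth.perturbations],
        "injected_metrics": [
            {"perturbation_index": k[0], "label": k[1], **v}
            for k, v in truth.injected_metrics.items()],
        "handrail_grabs": [list(map(float, g[:2])) + [int(g[2])]
                           for g in truth.handrail_grabs],
        "corrupted_segments": [
            {"kind": c[0], "start": float(c[1]), "end": float(c[2]),
             "perturbation_index": int(c[3]), "detail": str(c[4])}
            for c in truth.corrupted_segments],
    }


def _truth_from_dict(d: dict) -> GroundTruth:
    truth = GroundTruth()
    truth.heel_strikes = {s: np.asarray(v, dtype=float)
                          for s, v in d["heel_strikes"].items()}
    truth.toe_offs = {s: np.asarray(v, dtype=float) for s, v in d["toe_offs"].items()}
    truth.perturbations = [GroundTruthPerturbation(**p) for p in d["perturbations"]]
    for row in d["injected_metrics"]:
        row = dict(row)
        key = (int(row.pop("perturbation_index")), row.pop("label"))
        truth.injected_metrics[key] = row
    truth.handrail_grabs = [(g[0], g[1], int(g[2])) for g in d["handrail_grabs"]]
    truth.corrupted_segments = [
        (c["kind"], c["start"], c["end"], c["perturbation_index"], c["detail"])
        for c in d["corrupted_segments"]]
    return truth
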