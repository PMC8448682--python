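"""Reading and writing session data and analysis tables.

A generated session is stored as plain tables plus one hierarchical array
container: ``trials.csv`` (per-trial metadata and generating ground truth),
``spikes.csv`` (long format: trial_id, neuron_id, t_ms), ``traces.h5`` (one
dataset per trial, (n, 2) eye position with the start time as an attribute)
and ``cohort.json`` (the generative neuron parameters).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .oculomotor import SaccadeEvent
from .synthetic import NeuronSpec, TrialRecord

__all__ = [
    "write_session",
    "read_session",
    "write_cohort",
    "read_cohort",
    "saccade_table",
]

FLOAT_FMT = "%.6g"


def write_cohort(cohort, path) -> None:
    payload = [dataclasses.asdict(spec) for spec in cohort]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cohort(path) -> list[NeuronSpec]:
    payload = json.loads(Path(path).read_text())
    specs = []
    for d in payload:
        d["preferred_vector"] = tuple(d["preferred_vector"])
        d["spatial_center"] = tuple(d["spatial_center"])
        specs.append(NeuronSpec(**d))
    return specs


def write_session(trials, outdir, cohort=None) -> dict[str, Path]:
    """Write a simulated session to ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, spike_rows = [], []
    for tr in trials:
        gt = tr.ground_truth
        rows.append({
            "trial_id": tr.trial_id,
            "condition": tr.condition,
            "target_x": np.nan if tr.target_position is None else tr.target_position[0],
            "target_y": np.nan if tr.target_position is None else tr.target_position[1],
            "motion_direction": np.nan if tr.motion_direction is None else tr.motion_direction,
            "target_speed": tr.target_speed,
            "fixation_x": tr.fixation_point[0],
            "fixation_y": tr.fixation_point[1],
            "trace_t0": tr.trace_t0,
            "gt_onset": np.nan if gt is None else gt.onset,
            "gt_offset": np.nan if gt is None else gt.offset,
            "gt_end_x": np.nan if gt is None else gt.post_position[0],
            "gt_end_y": np.nan if gt is None else gt.post_position[1],
        })
        for j, spikes in enumerate(tr.spike_times):
            for t in np.asarray(spikes):
                spike_rows.append((tr.trial_id, j, float(t)))
    files = {}
    files["trials"] = outdir / "trials.csv"
    pd.DataFrame(rows).to_csv(files["trials"], index=False, float_format=FLOAT_FMT)
    files["spikes"] = outdir / "spikes.csv"
    pd.DataFrame(spike_rows, columns=["trial_id", "neuron_id", "t_ms"]).to_csv(
        files["spikes"], index=False, float_format="%.4f")
    files["traces"] = outdir / "traces.h5"
    with h5py.File(files["traces"], "w") as h5:
        for tr in trials:
            ds = h5.create_dataset(tr.trial_id, data=tr.eye_trace)
            ds.attrs["t0"] = tr.trace_t0
    if cohort is not None:
        files["cohort"] = outdir / "cohort.json"
        write_cohort(cohort, files["cohort"])
    return files


def read_session(indir) -> list[TrialRecord]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "trials.csv")
    spikes = pd.read_csv(indir / "spikes.csv")
    n_neurons = int(spikes["neuron_id"].max()) + 1 if len(spikes) else 0
    by_trial = {tid: g for tid, g in spikes.groupby("trial_id")}
    trials = []
    with h5py.File(indir / "traces.h5", "r") as h5:
        for _, row in meta.iterrows():
            tid = row["trial_id"]
            trace = np.asarray(h5[tid])
            t0 = float(h5[tid].attrs["t0"])
            g = by_trial.get(tid)
            spike_times = [np.empty(0)] * n_neurons
            if g is not None:
                for j, gg in g.groupby("neuron_id"):
                    spike_times[int(j)] = np.sort(gg["t_ms"].to_numpy(dtype=float))
            gt = None
            if np.isfinite(row["gt_onset"]):
                gt = SaccadeEvent(
                    onset=row["gt_onset"], offset=row["gt_offset"],
                    pre_position=(row["fixation_x"], row["fixation_y"]),
                    post_position=(row["gt_end_x"], row["gt_end_y"]),
                    latency=row["gt_onset"],
                    duration=row["gt_offset"] - row["gt_onset"],
                    end_time=row["gt_offset"],
                )
            trials.append(TrialRecord(
                trial_id=tid, condition=row["condition"],
                target_position=None if not np.isfinite(row["target_x"])
                else (row["target_x"], row["target_y"]),
                motion_direction=None if not np.isfinite(row["motion_direction"])
                else float(row["motion_direction"]),
                target_speed=float(row["target_speed"]),
                fixation_point=(float(row["fixation_x"]), float(row["fixation_y"])),
                trace_t0=t0, eye_trace=trace, spike_times=spike_times,
                ground_truth=gt,
            ))
    return trials


def saccade_table(trials, events) -> pd.DataFrame:
    """Per-trial table of detected saccade events."""
    rows = []
    for tr, ev in zip(trials, events):
        rows.append({
            "trial_id": tr.trial_id,
            "condition": tr.condition,
            "onset_ms": ev.onset,
            "offset_ms": ev.offset,
            "latency_ms": ev.latency,
            "duration_ms": ev.duration,
            "end_time_ms": ev.end_time,
            "pre_x": ev.pre_position[0], "pre_y": ev.pre_position[1],
            "end_x": ev.post_position[0], "end_y": ev.post_position[1],
        })
    return pd.DataFrame(rows)
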