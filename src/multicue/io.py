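"""Plain-file I/O: designs, schedules, placements, recordings, reports.

Tables are CSV; recordings are a raw float64 .npy array with a JSON
sidecar carrying the sampling rate, unit, and cue events.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CueEvent, CueSchedule, Design, GridSpec
from .eegsim import EegRecording

__all__ = [
    "write_design",
    "read_design",
    "write_schedule",
    "read_schedule",
    "save_recording",
    "load_recording",
    "write_json",
]


def write_design(design: Design, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design.items.to_csv(out / "items.csv", index=False)
    design.sets.to_csv(out / "sets.csv", index=False)
    cand = pd.DataFrame(
        [
            {"set_id": sid, "cand_idx": i, "x": xy[0], "y": xy[1]}
            for sid, pts in design.candidates.items()
            for i, xy in enumerate(pts)
        ]
    )
    cand.to_csv(out / "candidates.csv", index=False)
    with open(out / "grid.json", "w") as fh:
        json.dump(design.grid.__dict__, fh, indent=2)


def read_design(in_dir: str | Path) -> Design:
    src = Path(in_dir)
    with open(src / "grid.json") as fh:
        grid = GridSpec(**json.load(fh))
    items = pd.read_csv(src / "items.csv")
    sets = pd.read_csv(src / "sets.csv")
    cand = pd.read_csv(src / "candidates.csv")
    candidates = {
        sid: grp.sort_values("cand_idx")[["x", "y"]].to_numpy(float)
        for sid, grp in cand.groupby("set_id")
    }
    return Design(grid=grid, sets=sets, items=items, candidates=candidates)


def write_schedule(schedule: CueSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path: str | Path) -> CueSchedule:
    df = pd.read_csv(path)
    events = [
        CueEvent(
            sound_id=r.sound_id, size_k=int(r.size_k), onset_s=float(r.onset_s),
            pass_idx=int(r["pass"]), rep_idx=int(r.rep), iti_s=float(r.iti_s),
        )
        for _, r in df.iterrows()
    ]
    n_passes = int(df["pass"].max()) + 1 if len(df) else 0
    return CueSchedule(events=events, pass_count=n_passes)


def save_recording(rec: EegRecording, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), rec.samples)
    sidecar = {
        "fs": rec.fs,
        "unit": "uV",
        "events": [
            {
                "sound_id": e.sound_id, "size_k": e.size_k, "onset_s": e.onset_s,
                "pass": e.pass_idx, "rep": e.rep_idx, "iti_s": e.iti_s,
            }
            for e in rec.events
        ],
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_recording(prefix: str | Path) -> EegRecording:
    prefix = Path(prefix)
    samples = np.load(prefix.with_suffix(".npy"))
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    events = [
        CueEvent(
            sound_id=e["sound_id"], size_k=int(e["size_k"]), onset_s=float(e["onset_s"]),
            pass_idx=int(e["pass"]), rep_idx=int(e["rep"]), iti_s=float(e["iti_s"]),
        )
        for e in sidecar["events"]
    ]
    return EegRecording(samples=samples, fs=float(sidecar["fs"]), events=events)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
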