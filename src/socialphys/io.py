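"""Readers and writers for the session file formats.

Positions, spikes, bouts and result tables travel as CSV; calcium trace
matrices as HDF5 (neurons x frames with the frame clock alongside); ground
truth and summaries as JSON. Floats are written with a fixed format so a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BoutSet, PositionSeries
from .core import SessionTimeline
from .preprocess import SpikeTrain, TraceMatrix

_FLOAT_FMT = "%.10g"

POSITION_POINTS = ("subj_nose", "subj_body", "led",
                   "tgt_nose", "tgt_body", "tgt_tail")


def write_positions_csv(path: str | Path, timeline: SessionTimeline,
                        pos: PositionSeries) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(timeline.n_frames), "t_s": timeline.t,
    }
    for k in POSITION_POINTS:
        cols[f"{k}_x"] = pos[k][:, 0]
        cols[f"{k}_y"] = pos[k][:, 1]
    cols["valid"] = pos.mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_positions_csv(path: str | Path,
                       frame_rate: float = 30.0) -> tuple[SessionTimeline, PositionSeries]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"positions file not found: {path}")
    df = pd.read_csv(path)
    timeline = SessionTimeline(df["t_s"].to_numpy(), frame_rate)
    points = {k: np.stack([df[f"{k}_x"], df[f"{k}_y"]], axis=1)
              for k in POSITION_POINTS}
    mask = df["valid"].to_numpy().astype(bool) if "valid" in df else \
        np.ones(len(df), bool)
    return timeline, PositionSeries(points, mask)


def write_spikes_csv(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = [(tr.unit_id, tr.unit_class, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["unit_id", "unit_class", "t_s"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spikes_csv(path: str | Path) -> list[SpikeTrain]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spikes file not found: {path}")
    df = pd.read_csv(path)
    trains = []
    for (uid, cls), grp in df.groupby(["unit_id", "unit_class"], sort=True):
        trains.append(SpikeTrain(str(uid), str(cls), grp["t_s"].to_numpy()))
    return trains


def write_traces_h5(path: str | Path, traces: TraceMatrix,
                    timeline: SessionTimeline) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.values)
        f.create_dataset("neuron_ids",
                         data=np.array(traces.neuron_ids, dtype="S"))
        f.create_dataset("t_s", data=timeline.t)
        f.attrs["frame_rate"] = timeline.frame_rate
        f.attrs["zscored"] = traces.zscored


def read_traces_h5(path: str | Path) -> tuple[TraceMatrix, SessionTimeline]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"traces file not found: {path}")
    with h5py.File(path, "r") as f:
        values = f["traces"][()]
        ids = [s.decode() for s in f["neuron_ids"][()]]
        timeline = SessionTimeline(f["t_s"][()], float(f.attrs["frame_rate"]))
        z = bool(f.attrs.get("zscored", False))
    return TraceMatrix(ids, values, zscored=z), timeline


def write_bouts_csv(path: str | Path, bouts: BoutSet,
                    timeline: SessionTimeline) -> None:
    df = pd.DataFrame({
        "onset_s": timeline.t[bouts.intervals[:, 0]] if bouts.n_bouts else [],
        "offset_s": (timeline.t[np.minimum(bouts.intervals[:, 1],
                                           timeline.n_frames - 1)]
                     if bouts.n_bouts else []),
        "tag": bouts.tags,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_bouts_csv(path: str | Path, timeline: SessionTimeline) -> BoutSet:
    df = pd.read_csv(path)
    on = timeline.frame_of_time(df["onset_s"].to_numpy())
    off = timeline.frame_of_time(df["offset_s"].to_numpy()) + 1
    iv = np.stack([on, off], axis=1) if len(df) else np.empty((0, 2), int)
    return BoutSet(iv, list(df["tag"]), timeline.n_frames)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
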