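"""End-to-end orchestration: simulate/load -> bouts -> preprocess -> classify
-> correlate -> report, reproducible from one seed.

A run writes every intermediate artifact (positions, spikes, traces, bouts,
per-unit modulation table, pair-correlation table, class summary) plus a
manifest recording the config hash, library versions, and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import assemble_bouts, detect_interaction_frames
from .core import AnalysisParams, SessionTimeline, substreams
from .crosscorr import (EPOCH_MODES, build_epoch_mask, class_summary,
                        surrogate_significance)
from .io import (read_positions_csv, read_spikes_csv, read_traces_h5,
                 write_bouts_csv, write_json, write_positions_csv,
                 write_spikes_csv, write_traces_h5, _FLOAT_FMT)
from .modulation import classify_modulation, population_summary
from .preprocess import (TraceMatrix, align_streams, bin_spikes, smooth_rate,
                         zscore_series, zscore_traces)
from .synth import SynthConfig, simulate_session

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input mode, analysis constants, seed, output dir."""

    out_dir: Path
    mode: str = "synthetic"             # "synthetic" or "real"
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    synth: SynthConfig = field(default_factory=SynthConfig)
    positions_path: Path | None = None  # real-data inputs
    spikes_path: Path | None = None
    traces_path: Path | None = None
    epoch_modes: tuple = EPOCH_MODES
    min_duration: float = 0.2
    merge_gap: float = 0.5

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kw = dict(raw.get("run", {}))
        kw["out_dir"] = Path(kw.get("out_dir", "run"))
        for p in ("positions_path", "spikes_path", "traces_path"):
            if p in kw:
                kw[p] = Path(kw[p])
        if "params" in raw:
            pr = dict(raw["params"])
            if "peth_window" in pr:
                pr["peth_window"] = tuple(pr["peth_window"])
            kw["params"] = AnalysisParams(**pr)
        if "synth" in raw:
            sy = dict(raw["synth"])
            for k in ("suppression_duration", "excitation_duration",
                      "bout_duration", "offbout_distance"):
                if k in sy:
                    sy[k] = tuple(sy[k])
            kw["synth"] = SynthConfig(**sy)
        return cls(**kw)


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, tuple)):
            return str(o) if isinstance(o, Path) else list(o)
        raise TypeError
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artifacts + manifest under ``out_dir``.

    Deterministic given the seed: the seed fans into named substreams
    (simulation, classification shuffles, correlation surrogates) and all
    float output uses fixed formatting. Stage failures abort with a
    stage-tagged diagnostic.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = substreams(config.seed, "synth", "classify", "correlate")
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"socialphys": __version__, "numpy": np.__version__},
        "stages": {},
        "substreams": ["synth", "classify", "correlate"],
    }

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.mode == "synthetic":
            synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
            session = simulate_session(synth_cfg)
            timeline, pos = session.timeline, session.positions
            trains = session.spike_trains
            traces = TraceMatrix(session.acc_ids, session.traces)
            write_positions_csv(out / "positions.csv", timeline, pos)
            write_spikes_csv(out / "spikes.csv", trains)
            write_traces_h5(out / "traces.h5", traces, timeline)
            (out / "ground_truth.json").write_text(session.truth.to_json())
        else:
            for name in ("positions_path", "spikes_path", "traces_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {p}")
            traces, timeline = read_traces_h5(config.traces_path)
            timeline, pos = read_positions_csv(config.positions_path,
                                               timeline.frame_rate)
            trains = read_spikes_csv(config.spikes_path)
    except Exception as e:
        raise RuntimeError(f"[stage:inputs] {e}") from e
    manifest["stages"]["inputs"] = {
        "n_frames": timeline.n_frames,
        "n_spike_trains": len(trains),
        "n_acc_neurons": traces.n_neurons,
    }

    # ---- stage: bouts --------------------------------------------------
    try:
        ind, tag_idx = detect_interaction_frames(
            pos, config.params.proximity_threshold)
        bouts = assemble_bouts(ind, timeline.frame_rate, config.min_duration,
                               config.merge_gap, tag_idx)
        write_bouts_csv(out / "bouts.csv", bouts, timeline)
    except Exception as e:
        raise RuntimeError(f"[stage:bouts] {e}") from e
    manifest["stages"]["bouts"] = {
        "n_bouts": bouts.n_bouts,
        "interaction_fraction": float(bouts.indicator.mean()),
    }

    # ---- stage: preprocess --------------------------------------------
    try:
        scorable = [t for t in trains if t.unit_class in ("PC_SS", "DN")]
        rates = [
            zscore_series(smooth_rate(bin_spikes(t, timeline),
                                      config.params.kernel_sigma,
                                      config.params.bin_width))
            for t in scorable
        ]
        ztr = zscore_traces(traces)
        rates, ztr, timeline_al = align_streams(rates, ztr, timeline)
        n_degenerate = (sum(r.degenerate for r in rates)
                        + int(ztr.degenerate.sum()))
    except Exception as e:
        raise RuntimeError(f"[stage:preprocess] {e}") from e
    manifest["stages"]["preprocess"] = {
        "n_rate_series": len(rates),
        "n_degenerate": n_degenerate,
    }

    # ---- stage: classify ----------------------------------------------
    try:
        indicator = bouts.indicator[: timeline_al.n_frames]
        results = []
        for r in rates:
            results.append(classify_modulation(
                r.values, indicator, config.params, rngs["classify"],
                timeline_al.frame_rate, unit_id=r.unit_id, context="social"))
        for i, nid in enumerate(ztr.neuron_ids):
            results.append(classify_modulation(
                ztr.values[i], indicator, config.params, rngs["classify"],
                timeline_al.frame_rate, unit_id=nid, context="social"))
        mod_df = pd.DataFrame([
            {"unit_id": m.unit_id, "context": m.context, "auc": m.auc,
             "p_low": m.p_low, "p_high": m.p_high, "label": m.label}
            for m in results
        ])
        mod_df.to_csv(out / "modulation.csv", index=False,
                      float_format=_FLOAT_FMT)
        write_json(out / "population_summary.json",
                   population_summary(results))
        labels = {m.unit_id: m.label for m in results}
    except Exception as e:
        raise RuntimeError(f"[stage:classify] {e}") from e
    manifest["stages"]["classify"] = {
        "n_units": len(results),
        "n_positive": sum(m.label == "positive" for m in results),
        "n_negative": sum(m.label == "negative" for m in results),
    }

    # ---- stage: correlate ---------------------------------------------
    try:
        pair_rows = []
        pair_results = []
        for mode in config.epoch_modes:
            mask = build_epoch_mask(bouts, mode, timeline_al,
                                    pad=config.params.offbout_pad,
                                    min_usable=config.params.min_usable_frames)
            for r in rates:
                for i, nid in enumerate(ztr.neuron_ids):
                    pr = surrogate_significance(
                        r.values, ztr.values[i], mask, config.params,
                        rngs["correlate"], timeline_al.frame_rate,
                        cb_unit=r.unit_id, cb_label=labels[r.unit_id],
                        acc_neuron=nid, acc_label=labels[nid])
                    pair_results.append(pr)
                    pair_rows.append({
                        "cb_unit": pr.cb_unit, "cb_label": pr.cb_label,
                        "acc_neuron": pr.acc_neuron, "acc_label": pr.acc_label,
                        "mode": pr.mode, "r": pr.r, "p": pr.p,
                        "sig": int(pr.significant), "sign": pr.sign,
                    })
        pd.DataFrame(pair_rows).to_csv(out / "pairs.csv", index=False,
                                       float_format=_FLOAT_FMT)
        summary = class_summary(pair_results)
        write_json(out / "class_summary.json", {
            "|".join(k): {kk: vv for kk, vv in v.items() if kk != "r_values"}
            for k, v in summary.items()
        })
        n_excluded = sum(p.degenerate for p in pair_results)
    except Exception as e:
        raise RuntimeError(f"[stage:correlate] {e}") from e
    manifest["stages"]["correlate"] = {
        "n_pairs": len(pair_results),
        "n_degenerate_excluded": n_excluded,
    }

    write_json(out / "manifest.json", manifest)
    return out
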