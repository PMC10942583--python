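"""Figure rendering for a completed pipeline run.

Produces the standard summary panels from the run directory's artifacts:
event-aligned PETH heatmaps with mean traces, modulation-label proportion
charts, per-class cumulative correlation histograms with off-bout insets,
and significant-pair proportion matrices. Missing artifacts skip their
panel with a notice instead of failing the report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import SessionTimeline
from .io import read_bouts_csv, read_spikes_csv, read_positions_csv
from .modulation import compute_peth
from .preprocess import bin_spikes, smooth_rate, zscore_series

log = logging.getLogger(__name__)


def render_report(run_dir: str | Path, params=None) -> list[Path]:
    """Render all available panels into ``run_dir``; returns written paths.

    Idempotent: re-running overwrites the same files.
    """
    run_dir = Path(run_dir)
    written: list[Path] = []
    for name, fn in (("proportions.png", _plot_proportions),
                     ("correlation_cdfs.png", _plot_cdfs),
                     ("sig_matrices.png", _plot_matrices),
                     ("peth.png", _plot_peths)):
        try:
            fig = fn(run_dir)
        except FileNotFoundError as e:
            log.warning("panel %s skipped: %s", name, e)
            continue
        out = run_dir / name
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written


def _plot_proportions(run_dir: Path):
    df = pd.read_csv(run_dir / "modulation.csv")
    fig, ax = plt.subplots(figsize=(4, 3))
    counts = df["label"].value_counts(normalize=True)
    order = ["positive", "negative", "ns"]
    ax.bar(order, [counts.get(k, 0.0) for k in order],
           color=["tab:red", "tab:blue", "0.7"])
    ax.set_ylabel("proportion of units")
    ax.set_title("Modulation by social interaction")
    fig.tight_layout()
    return fig


def _plot_cdfs(run_dir: Path):
    df = pd.read_csv(run_dir / "pairs.csv")
    cb_labels = ["positive", "negative"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, cb in zip(axes, cb_labels):
        sub_full = df[(df.cb_label == cb) & (df["mode"] == "full")]
        inset = ax.inset_axes([0.58, 0.12, 0.38, 0.38])
        for acc, color in (("positive", "tab:red"), ("negative", "tab:blue"),
                           ("ns", "0.6")):
            for frame, mode in ((ax, "full"), (inset, "offbout")):
                r = df[(df.cb_label == cb) & (df.acc_label == acc)
                       & (df["mode"] == mode)]["r"].dropna().to_numpy()
                if r.size == 0:
                    if frame is ax:
                        ax.text(0.02, 0.9 if acc == "positive" else 0.8,
                                f"no {acc} pairs", transform=ax.transAxes,
                                fontsize=7, color=color)
                    continue
                x = np.sort(r)
                y = np.arange(1, x.size + 1) / x.size
                frame.step(np.r_[x[0], x], np.r_[0, y], color=color,
                           label=f"ACC {acc}" if frame is ax else None)
        ax.set_title(f"cerebellar {cb}")
        ax.set_xlabel("Pearson r")
        inset.set_title("off-bout", fontsize=7)
        inset.tick_params(labelsize=6)
        if sub_full.size:
            ax.legend(fontsize=7, loc="upper left")
    axes[0].set_ylabel("cumulative fraction")
    fig.tight_layout()
    return fig


def _plot_matrices(run_dir: Path):
    payload = json.loads((run_dir / "class_summary.json").read_text())
    cb_labels, acc_labels = ["positive", "negative"], ["positive", "negative", "ns"]
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    for ax, direction in zip(axes, ("pct_sig_positive", "pct_sig_negative")):
        m = np.full((len(cb_labels), len(acc_labels)), np.nan)
        for i, cb in enumerate(cb_labels):
            for j, acc in enumerate(acc_labels):
                cell = payload.get(f"{cb}|{acc}|full")
                if cell:
                    m[i, j] = cell[direction]
        im = ax.imshow(m, vmin=0, vmax=100, cmap="viridis")
        ax.set_xticks(range(len(acc_labels)), acc_labels)
        ax.set_yticks(range(len(cb_labels)), cb_labels)
        ax.set_title(direction.replace("pct_sig_", "% significant "))
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                ax.text(j, i, "n/a" if np.isnan(m[i, j]) else f"{m[i, j]:.0f}",
                        ha="center", va="center", color="w", fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig


def _plot_peths(run_dir: Path):
    trains = read_spikes_csv(run_dir / "spikes.csv")
    timeline, _ = read_positions_csv(run_dir / "positions.csv")
    bouts = read_bouts_csv(run_dir / "bouts.csv", timeline)
    mod = pd.read_csv(run_dir / "modulation.csv").set_index("unit_id")
    onsets = bouts.onsets_s(timeline)
    panels = []
    for tr in trains:
        if tr.unit_class not in ("PC_SS", "DN"):
            continue
        lab = mod.loc[tr.unit_id, "label"] if tr.unit_id in mod.index else "ns"
        if lab != "ns":
            z = zscore_series(smooth_rate(bin_spikes(tr, timeline), 0.1, 1 / 30))
            panels.append((tr.unit_id, lab,
                           compute_peth(z.values, timeline, onsets, (2.0, 4.0))))
        if len(panels) == 4:
            break
    if not panels:
        raise FileNotFoundError("no significantly modulated units to align")
    fig, axes = plt.subplots(2, len(panels), figsize=(3 * len(panels), 4.5),
                             squeeze=False)
    for k, (uid, lab, peth) in enumerate(panels):
        axes[0, k].imshow(peth.matrix, aspect="auto", cmap="coolwarm",
                          extent=[peth.lags[0], peth.lags[-1],
                                  peth.n_events, 0])
        axes[0, k].set_title(f"{uid} ({lab})", fontsize=9)
        axes[1, k].plot(peth.lags, peth.mean, color="k")
        axes[1, k].fill_between(peth.lags, peth.mean - peth.sem,
                                peth.mean + peth.sem, alpha=0.3)
        axes[1, k].axvline(0, ls="--", color="0.5")
        axes[1, k].set_xlabel("time from bout onset (s)")
    axes[1, 0].set_ylabel("z-scored rate")
    fig.tight_layout()
    return fig
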