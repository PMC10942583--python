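"""Pairwise cerebellum-ACC correlation with circular-shift surrogates.

Each (cerebellar unit, ACC neuron) pair gets a Pearson correlation between
the unit's smoothed z-scored rate and the neuron's z-scored calcium trace,
either over the full session or restricted to non-social (off-bout) frames.
Significance comes from surrogates built by circularly shifting the intact
calcium trace (shift-then-mask, preserving within-epoch autocorrelation)
and recomputing r; the two-sided add-one p is compared with ``corr_alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BoutSet
from .core import AnalysisParams, SessionTimeline
from .modulation import draw_shifts

EPOCH_MODES = ("full", "offbout")


@dataclass
class EpochMask:
    """Per-frame usable-frame flags for an analysis epoch."""

    usable: np.ndarray
    mode: str
    pad: float = 0.0

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, bool)
        if self.mode not in EPOCH_MODES:
            raise ValueError(f"unknown epoch mode {self.mode!r}")

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass
class PairCorrResult:
    cb_unit: str
    cb_label: str
    acc_neuron: str
    acc_label: str
    mode: str
    r: float
    p: float
    significant: bool
    sign: int  # +1 / -1 / 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of [-1, 1]")


def build_epoch_mask(
    bouts: BoutSet,
    mode: str,
    timeline: SessionTimeline,
    pad: float = 1.0,
    min_usable: int = 100,
) -> EpochMask:
    """Full-session mask, or the off-bout complement with a pad (s) around bouts.

    The pad absorbs the seconds-long response tails that follow bout onsets,
    so off-bout frames are genuinely non-social. Raises if fewer than
    ``min_usable`` frames survive.
    """
    n = timeline.n_frames
    if mode == "full":
        return EpochMask(np.ones(n, bool), "full")
    pad_f = int(round(pad * timeline.frame_rate))
    usable = np.ones(n, bool)
    for a, b in bouts.intervals:
        usable[max(0, a - pad_f): min(n, b + pad_f)] = False
    if usable.sum() < min_usable:
        raise ValueError(
            f"off-bout mask leaves only {int(usable.sum())} usable frames "
            f"(minimum {min_usable})"
        )
    return EpochMask(usable, "offbout", pad)


def pair_correlation(rate: np.ndarray, trace: np.ndarray, mask: EpochMask) -> float:
    """Pearson r between two frame series over the usable frames only.

    Masked-out frames are removed and the remaining segments concatenated.
    A series constant on the mask is degenerate (raises); callers that need
    to survey many pairs should catch and flag it.
    """
    x = np.asarray(rate, float)[mask.usable]
    y = np.asarray(trace, float)[mask.usable]
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("series constant on the usable frames")
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / (np.linalg.norm(x) * np.linalg.norm(y)))


def _masked_corr_for_shifts(
    rate: np.ndarray, trace: np.ndarray, usable: np.ndarray, shifts: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Pearson r between ``rate`` and each circular shift of ``trace`` on the mask.

    The trace is shifted intact first, then the mask applied (shift-then-mask),
    so surrogate within-epoch autocorrelation matches the observed trace's.
    """
    L = trace.size
    idx = np.flatnonzero(usable)
    x = rate[idx].astype(float)
    x = x - x.mean()
    xn = np.linalg.norm(x)
    out = np.empty(shifts.size)
    for s0 in range(0, shifts.size, chunk):
        sh = shifts[s0:s0 + chunk]
        # roll(trace, s)[i] == trace[(i - s) % L]
        ys = trace[(idx[None, :] - sh[:, None]) % L]
        ys = ys - ys.mean(axis=1, keepdims=True)
        denom = xn * np.linalg.norm(ys, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[s0:s0 + chunk] = (ys @ x) / denom
    return out


def surrogate_significance(
    rate: np.ndarray,
    trace: np.ndarray,
    mask: EpochMask,
    params: AnalysisParams,
    rng: np.random.Generator,
    frame_rate: float = 30.0,
    cb_unit: str = "",
    cb_label: str = "ns",
    acc_neuron: str = "",
    acc_label: str = "ns",
) -> PairCorrResult:
    """Observed pair correlation plus its circular-shift surrogate p-value.

    Surrogates circularly shift the full-length calcium trace by at least
    ``params.min_shift`` seconds, apply the epoch mask, and recompute r;
    the two-sided p uses the add-one rule and significance is declared at
    ``params.corr_alpha`` with the sign of the observed r.
    """
    rate = np.asarray(rate, float)
    trace = np.asarray(trace, float)
    try:
        obs = pair_correlation(rate, trace, mask)
    except ValueError:
        return PairCorrResult(cb_unit, cb_label, acc_neuron, acc_label, mask.mode,
                              np.nan, np.nan, False, 0, degenerate=True)
    min_shift_frames = int(round(params.min_shift * frame_rate))
    shifts = draw_shifts(params.n_shuffles, trace.size, min_shift_frames, rng)
    null = _masked_corr_for_shifts(rate, trace, mask.usable, shifts)
    null = null[np.isfinite(null)]
    p = (1 + np.count_nonzero(np.abs(null) >= abs(obs))) / (1 + null.size)
    sig = p < params.corr_alpha
    return PairCorrResult(cb_unit, cb_label, acc_neuron, acc_label, mask.mode,
                          obs, float(p), bool(sig), int(np.sign(obs)) if sig else 0)


def class_summary(results: list[PairCorrResult]) -> dict:
    """Correlation distributions and significant-pair matrices by class pair.

    Results are keyed by (cerebellar label, ACC label, epoch mode). For each
    cell the full r distribution is kept (for cumulative histograms) along
    with the percentage of pairs significantly positive and negative. Class
    cells with no pairs are reported as missing, never as zero.
    """
    cells: dict[tuple[str, str, str], list[PairCorrResult]] = {}
    for r in results:
        if r.degenerate:
            continue
        cells.setdefault((r.cb_label, r.acc_label, r.mode), []).append(r)
    out: dict = {}
    for key, rs in cells.items():
        rvals = np.array([x.r for x in rs])
        n = len(rs)
        pos = sum(1 for x in rs if x.significant and x.sign > 0)
        neg = sum(1 for x in rs if x.significant and x.sign < 0)
        out[key] = {
            "n_pairs": n,
            "r_values": rvals,
            "median_r": float(np.median(rvals)),
            "pct_sig_positive": 100.0 * pos / n,
            "pct_sig_negative": 100.0 * neg / n,
        }
    return out
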