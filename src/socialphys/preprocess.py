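"""Spike binning, Gaussian-kernel smoothing, z-scoring, stream alignment.

Spike trains are binned at the imaging frame clock (~33 ms bins at ~30 Hz) so
rate series and calcium traces share one grid, smoothed with a Gaussian
kernel (sigma 100 ms by default), and z-scored per unit over the whole
session. A CS-SS cross-correlogram is provided as a QA check for putative
Purkinje cells (the complex spike induces a pause in simple spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import correlate1d

from .core import SessionTimeline

log = logging.getLogger(__name__)

UNIT_CLASSES = ("PC_SS", "PC_CS", "DN", "ACC")

_STAGES = ("counts", "rate", "smoothed", "zscored")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) for one unit."""

    unit_id: str
    unit_class: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) < 0):
            t = np.sort(t)
        object.__setattr__(self, "times", t)
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit class {self.unit_class!r}")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class RateSeries:
    """Per-frame activity of one unit with a processing-stage flag.

    The stage only moves forward through counts -> rate -> smoothed ->
    zscored; each operation checks it received the stage it expects, so a
    series cannot be smoothed twice or z-scored before smoothing by accident.
    """

    unit_id: str
    values: np.ndarray
    stage: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _advance(self, values: np.ndarray, stage: str, **kw) -> "RateSeries":
        if _STAGES.index(stage) <= _STAGES.index(self.stage):
            raise ValueError(f"cannot move stage {self.stage!r} -> {stage!r}")
        return replace(self, values=values, stage=stage, **kw)


@dataclass
class TraceMatrix:
    """Calcium traces, neurons x frames."""

    neuron_ids: list[str]
    values: np.ndarray
    zscored: bool = False
    degenerate: np.ndarray | None = None  # per-neuron zero-variance flag

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.neuron_ids):
            raise ValueError("neuron_ids length must match rows of values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def bin_spikes(spikes: SpikeTrain, timeline: SessionTimeline) -> RateSeries:
    """Bin spike times at the frame clock and convert counts to rate (Hz).

    Bin edges are the frame timestamps themselves (nominally ~33 ms wide),
    with the last bin closed, guaranteeing 1:1 alignment with calcium frames.
    Spikes outside the session span are dropped (and counted in the log).
    """
    edges = timeline.bin_edges
    t = spikes.times
    inside = (t >= edges[0]) & (t <= edges[-1])
    dropped = int(t.size - inside.sum())
    if dropped:
        log.info("unit %s: dropped %d spikes outside session", spikes.unit_id, dropped)
    counts, _ = np.histogram(t[inside], bins=edges)
    widths = np.diff(edges)
    return RateSeries(spikes.unit_id, counts / widths, stage="rate")


def gaussian_kernel(sigma: float, bin_width: float) -> np.ndarray:
    """Unit-area Gaussian kernel sampled at the frame spacing, truncated at ±4σ."""
    half = int(np.ceil(4 * sigma / bin_width))
    x = np.arange(-half, half + 1) * bin_width
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_rate(
    series: RateSeries, sigma: float, bin_width: float, mode: str = "reflect"
) -> RateSeries:
    """Convolve a rate series with a unit-area Gaussian (sigma in seconds).

    ``mode`` selects the edge treatment: ``reflect`` for display-quality
    smoothing, ``wrap`` (circular) when exact commutation with circular
    shifts is required (as inside shuffle tests). The unit-area kernel
    preserves the series sum up to edge effects.
    """
    if series.stage != "rate":
        raise ValueError(f"smooth_rate expects stage 'rate', got {series.stage!r}")
    if sigma < bin_width:
        log.warning("kernel sigma %.3g s under-resolved by bin width %.3g s", sigma, bin_width)
    k = gaussian_kernel(sigma, bin_width)
    out = correlate1d(series.values, k, mode=mode)
    return series._advance(out, "smoothed")


def zscore_series(series: RateSeries) -> RateSeries:
    """Z-score over the whole session using the population SD (divide by N).

    A zero-variance series is flagged degenerate (values set to 0) rather
    than raising, so downstream steps can exclude it explicitly.
    """
    v = series.values
    if v.size < 2:
        raise ValueError("need >= 2 frames to z-score")
    sd = v.std()
    if sd == 0:
        return series._advance(np.zeros_like(v), "zscored", degenerate=True)
    return series._advance((v - v.mean()) / sd, "zscored")


def zscore_traces(traces: TraceMatrix) -> TraceMatrix:
    """Per-neuron z-scoring of a trace matrix (population SD).

    Zero-variance neurons are flagged in ``degenerate`` and zeroed.
    """
    if traces.n_frames < 2:
        raise ValueError("need >= 2 frames to z-score")
    v = traces.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    degen = sd[:, 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return TraceMatrix(
        traces.neuron_ids, (v - mu) / sd, zscored=True, degenerate=degen
    )


def align_streams(
    rates: list[RateSeries], traces: TraceMatrix, timeline: SessionTimeline
) -> tuple[list[RateSeries], TraceMatrix, SessionTimeline]:
    """Truncate spike-rate series and calcium traces to their common frame span.

    Both streams are referenced to the same frame clock starting at frame 0;
    acquisition can stop one stream a few frames early, so everything is cut
    to the shortest length. Disjoint spans are an error.
    """
    lengths = [r.values.size for r in rates] + [traces.n_frames]
    n = min(lengths)
    if n <= 0:
        raise ValueError("streams have no overlapping frames")
    rates_out = [replace(r, values=r.values[:n]) for r in rates]
    traces_out = replace(traces, values=traces.values[:, :n])
    tl = SessionTimeline(timeline.t[:n], timeline.frame_rate)
    return rates_out, traces_out, tl


def cs_ss_crosscorrelogram(
    ss: SpikeTrain, cs: SpikeTrain, window: float = 0.1, bin: float = 0.002
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlogram of simple-spike times relative to complex spikes.

    Histograms all lags ``t_SS - t_CS`` within ±``window`` s, normalized to
    an SS rate in Hz per CS (counts / n_CS / bin). A putative Purkinje cell
    shows a pause — near-zero SS rate — for tens of ms after each CS.

    Returns ``(lag_centers, rate_hz)``.
    """
    if ss.n_spikes == 0 or cs.n_spikes == 0:
        raise ValueError("both spike trains must be nonempty")
    edges = np.arange(-window, window + bin / 2, bin)
    counts = np.zeros(edges.size - 1)
    t_ss, t_cs = ss.times, cs.times
    # window into the sorted SS train around each CS
    lo = np.searchsorted(t_ss, t_cs - window)
    hi = np.searchsorted(t_ss, t_cs + window)
    for c, a, b in zip(t_cs, lo, hi):
        counts += np.histogram(t_ss[a:b] - c, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / (cs.n_spikes * bin)
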