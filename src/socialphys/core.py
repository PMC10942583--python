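"""Shared session clock and parameter containers.

Every data stream in a session (behavioral positions, spike trains binned to
frames, calcium traces) is referenced to a single frame clock at roughly the
imaging rate (~30 Hz), so spike bins line up one-to-one with calcium frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SessionTimeline:
    """Frame clock shared by behavior, spikes, and calcium.

    Parameters
    ----------
    t : ndarray of float
        Frame timestamps in seconds, strictly increasing.
    frame_rate : float
        Nominal frame rate in Hz. The median frame interval must be within
        10% of ``1 / frame_rate``.
    """

    t: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("timeline needs at least two frame timestamps")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        med = float(np.median(dt))
        if abs(med - 1.0 / self.frame_rate) > 0.1 / self.frame_rate:
            raise ValueError(
                f"median frame interval {med:.4f} s inconsistent with nominal "
                f"rate {self.frame_rate:g} Hz"
            )

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Session span in seconds including the trailing frame's bin."""
        return float(self.t[-1] - self.t[0]) + 1.0 / self.frame_rate

    @property
    def bin_edges(self) -> np.ndarray:
        """Frame bin edges: the timestamps plus one trailing edge."""
        return np.append(self.t, self.t[-1] + 1.0 / self.frame_rate)

    def frame_of_time(self, times: np.ndarray) -> np.ndarray:
        """Map times (s) to frame indices (clipped to valid range)."""
        idx = np.searchsorted(self.bin_edges, np.asarray(times, float), "right") - 1
        return np.clip(idx, 0, self.n_frames - 1)

    @classmethod
    def regular(cls, duration: float, frame_rate: float = 30.0) -> "SessionTimeline":
        """Uniformly sampled timeline starting at t=0."""
        n = int(round(duration * frame_rate))
        return cls(np.arange(n) / frame_rate, frame_rate)


@dataclass
class AnalysisParams:
    """Analysis constants.

    Defaults follow the standard recipe for this kind of joint session:
    ~33 ms spike bins matched to ~30 Hz imaging frames, a 100 ms Gaussian
    smoothing kernel, 1000-iteration circular-shuffle nulls, and a per-tail
    significance criterion of 0.025 (two-tailed 0.05) for AUC modulation.
    ``corr_alpha`` is the two-sided level for pairwise-correlation surrogates.
    """

    bin_width: float = 0.033
    kernel_sigma: float = 0.100
    n_shuffles: int = 1000
    alpha_per_tail: float = 0.025
    corr_alpha: float = 0.05
    min_shift: float = 10.0
    proximity_threshold: float = 20.0
    peth_window: tuple[float, float] = (2.0, 4.0)
    min_class_fraction: float = 0.01
    min_usable_frames: int = 100
    offbout_pad: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bin_width", "kernel_sigma", "min_shift", "proximity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        for name in ("alpha_per_tail", "corr_alpha"):
            a = getattr(self, name)
            if not 0 < a < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")


def substreams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Fan a single seed out into named, independent random substreams.

    Stage-specific generators let any stage (behavior, spikes, calcium,
    shuffles) be regenerated on its own while keeping the whole pipeline
    reproducible from one integer seed.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}
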