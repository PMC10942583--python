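"""Interaction-bout detection and kinematics from position tracking.

A social (or object) interaction frame is one where the subject's nose comes
within a proximity threshold (default 20 mm) of the target's nose, body
centroid, or tail base; contiguous runs of such frames are assembled into
bouts. Speed and head angular speed are derived from the head-mounted LED
track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .core import SessionTimeline

CONTACT_TAGS = ("nose-nose", "nose-body", "nose-rear")

# target parts checked for proximity, in tag order
_PART_KEYS = ("tgt_nose", "tgt_body", "tgt_tail")


@dataclass
class PositionSeries:
    """Per-frame tracked coordinates in mm.

    ``points`` maps a point name (subj_nose, subj_body, led, tgt_nose,
    tgt_body, tgt_tail) to an (n_frames, 2) array. ``mask`` flags frames with
    valid tracking; masked-out frames are never scored as interactions.
    """

    points: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = self.mask.shape[0]
        self.mask = np.asarray(self.mask, dtype=bool)
        for k, v in self.points.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n, 2):
                raise ValueError(f"point {k!r} has shape {v.shape}, expected ({n}, 2)")
            self.points[k] = v

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.points[key]


@dataclass
class BoutSet:
    """Non-overlapping interaction intervals on the frame grid.

    Intervals are half-open ``[onset, offset)`` frame index pairs, sorted by
    onset. ``indicator`` is the per-frame binary vector regenerated from the
    intervals, so the two representations can never disagree.
    """

    intervals: np.ndarray  # (n_bouts, 2) int
    tags: list[str]
    n_frames: int

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=int).reshape(-1, 2)
        if iv.size and (np.any(iv[:, 0] >= iv[:, 1]) or np.any(iv[:, 0] < 0)
                        or np.any(iv[:, 1] > self.n_frames)):
            raise ValueError("bout intervals must be nonempty and within session")
        order = np.argsort(iv[:, 0]) if iv.size else np.array([], int)
        iv = iv[order]
        self.tags = [self.tags[i] for i in order]
        if iv.shape[0] > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("bout intervals overlap")
        self.intervals = iv

    @property
    def n_bouts(self) -> int:
        return self.intervals.shape[0]

    @property
    def indicator(self) -> np.ndarray:
        ind = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.intervals:
            ind[a:b] = True
        return ind

    def onsets_s(self, timeline: SessionTimeline) -> np.ndarray:
        return timeline.t[self.intervals[:, 0]] if self.n_bouts else np.array([])

    def durations_s(self, timeline: SessionTimeline) -> np.ndarray:
        if not self.n_bouts:
            return np.array([])
        return (self.intervals[:, 1] - self.intervals[:, 0]) / timeline.frame_rate


@dataclass
class KinematicsSeries:
    """Per-frame speed (mm/s) and head angular speed (deg/s).

    ``low_speed_mask`` marks frames where the LED barely moved; heading (and
    hence angular speed) is undefined there and reported as 0.
    """

    speed: np.ndarray
    angular_speed: np.ndarray
    low_speed_mask: np.ndarray


def detect_interaction_frames(
    pos: PositionSeries, threshold: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag frames where the subject nose is within ``threshold`` mm of a target part.

    Returns ``(indicator, tag_idx)``: a boolean per-frame vector and, for each
    frame, the index into :data:`CONTACT_TAGS` of the nearest target part
    (-1 where not flagged). Masked frames are never flagged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.any(pos.mask):
        raise ValueError("all frames masked: no valid tracking to score")
    nose = pos["subj_nose"]
    dists = np.stack(
        [np.linalg.norm(nose - pos[k], axis=1) for k in _PART_KEYS], axis=1
    )  # (n, 3) distance to nose/body/tail
    nearest = np.argmin(dists, axis=1)
    flagged = (np.min(dists, axis=1) <= threshold) & pos.mask
    tag_idx = np.where(flagged, nearest, -1)
    return flagged, tag_idx


def assemble_bouts(
    indicator: np.ndarray,
    frame_rate: float,
    min_duration: float = 0.2,
    merge_gap: float = 0.5,
    tag_idx: np.ndarray | None = None,
) -> BoutSet:
    """Turn a per-frame indicator into a cleaned :class:`BoutSet`.

    Maximal runs of flagged frames separated by gaps shorter than
    ``merge_gap`` (s) are merged, then runs shorter than ``min_duration`` (s)
    are dropped. Defaults suppress single-frame tracking jitter. Each bout is
    tagged by the modal contact tag of its flagged frames (``nose-nose`` if no
    tags were provided).
    """
    ind = np.asarray(indicator, dtype=bool)
    n = ind.size
    runs = _runs(ind)
    gap_frames = merge_gap * frame_rate
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_frames = min_duration * frame_rate
    kept = [(a, b) for a, b in merged if b - a >= min_frames]
    tags = []
    for a, b in kept:
        if tag_idx is None:
            tags.append(CONTACT_TAGS[0])
        else:
            seg = tag_idx[a:b]
            seg = seg[seg >= 0]
            tags.append(CONTACT_TAGS[np.bincount(seg, minlength=3).argmax()]
                        if seg.size else CONTACT_TAGS[0])
    iv = np.array(kept, int).reshape(-1, 2)
    return BoutSet(iv, tags, n)


def _runs(ind: np.ndarray) -> np.ndarray:
    """Half-open [start, stop) index pairs of maximal True runs."""
    if not ind.any():
        return np.empty((0, 2), int)
    d = np.diff(ind.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if ind[0]:
        starts = np.r_[0, starts]
    if ind[-1]:
        stops = np.r_[stops, ind.size]
    return np.stack([starts, stops], axis=1)


def compute_kinematics(
    pos: PositionSeries,
    timeline: SessionTimeline,
    median_width: int = 5,
    low_speed: float = 5.0,
) -> KinematicsSeries:
    """Speed and head angular speed from the head-mounted LED track.

    Speed is the centered-difference LED displacement over time. Heading is
    the direction of LED displacement (a single LED carries no orientation,
    so displacement direction is the proxy); angular speed is the absolute
    wrapped heading change per unit time. Frames moving slower than
    ``low_speed`` mm/s have undefined heading and report angular speed 0.
    Both series are median-filtered with ``median_width`` frames.
    """
    led = pos["led"]
    if np.count_nonzero(pos.mask) < 3:
        raise ValueError("need at least 3 valid frames for kinematics")
    t = timeline.t
    vel = np.gradient(led, t, axis=0)  # centered differences, mm/s
    speed = np.linalg.norm(vel, axis=1)
    heading = np.arctan2(vel[:, 1], vel[:, 0])
    low = speed < low_speed
    dh = np.diff(heading)
    dh = (dh + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
    ang = np.abs(np.r_[0.0, dh]) / np.gradient(t)
    ang = np.degrees(ang)
    ang[low] = 0.0
    if median_width > 1:
        speed = median_filter(speed, size=median_width, mode="nearest")
        ang = median_filter(ang, size=median_width, mode="nearest")
    return KinematicsSeries(speed=speed, angular_speed=ang, low_speed_mask=low)


@dataclass
class MovementEvents:
    """Frame indices of threshold-crossing movement events."""

    locomotion_onsets: np.ndarray
    locomotion_offsets: np.ndarray
    rotation_onsets: np.ndarray


def _hysteresis_events(
    x: np.ndarray, on_thresh: float, off_thresh: float, refractory_frames: float
) -> tuple[np.ndarray, np.ndarray]:
    """Onsets/offsets of a signal under hysteresis with a refractory period.

    An onset fires when ``x`` crosses above ``on_thresh`` after having spent
    at least ``refractory_frames`` below ``off_thresh``; offsets are
    symmetric (cross below off_thresh after >= refractory above on_thresh).
    """
    onsets, offsets = [], []
    state = x[0] >= on_thresh
    run = np.inf  # frames spent in the qualifying pre-state
    for i in range(1, x.size):
        if not state:
            if x[i] >= on_thresh and run >= refractory_frames:
                state = True
                onsets.append(i)
                run = 0.0
            elif x[i] < off_thresh:
                run += 1
        else:
            if x[i] < off_thresh and run >= refractory_frames:
                state = False
                offsets.append(i)
                run = 0.0
            elif x[i] >= on_thresh:
                run += 1
    return np.array(onsets, int), np.array(offsets, int)


def detect_movement_events(
    kin: KinematicsSeries,
    frame_rate: float,
    on_thresh: float = 50.0,
    off_thresh: float = 20.0,
    refractory: float = 1.0,
    rot_on_thresh: float = 90.0,
    rot_off_thresh: float = 30.0,
) -> MovementEvents:
    """Locomotion onsets/offsets and head-rotation onsets.

    Thresholds are hysteretic (``on_thresh > off_thresh``) so jitter around a
    single threshold cannot spawn spurious events; ``refractory`` (s) is the
    minimum qualifying time in the pre-state.
    """
    if on_thresh <= off_thresh or rot_on_thresh <= rot_off_thresh:
        raise ValueError("hysteresis requires on_thresh > off_thresh")
    rf = refractory * frame_rate
    on, off = _hysteresis_events(kin.speed, on_thresh, off_thresh, rf)
    rot_on, _ = _hysteresis_events(kin.angular_speed, rot_on_thresh, rot_off_thresh, rf)
    return MovementEvents(on, off, rot_on)
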