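"""Synthetic joint sessions: behavior + cerebellar spikes + cortical calcium.

Emulates a single recording session in a 48 x 48 cm arena — ~1 min of
baseline followed by ~7 min with a novel target — together with the neural
structure the analysis assumes: bout-locked Purkinje-cell simple-spike
suppression lasting 1-3 s, dentate-nucleus excitation lasting 2-4 s, ~30 Hz
calcium traces from an event-rate model, and cross-region coupling delivered
through a shared bout-locked latent. Every generated quantity is recorded in
a :class:`GroundTruth` so each analysis stage can be tested for recovery.

Trajectories are Ornstein-Uhlenbeck-style smoothed random walks with
reflecting arena walls; the target's distance to the subject's nose is
scripted around the planted bout schedule so proximity detection can recover
it. Calcium is a linear event model: Poisson events at a latent rate,
convolved with a causal double-exponential kernel, plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior import BoutSet, PositionSeries
from .core import SessionTimeline, substreams
from .preprocess import SpikeTrain

LABELS = ("positive", "negative", "ns")


@dataclass
class SynthConfig:
    """Generation parameters; defaults are the emulated study conditions.

    The arena is 480 mm square; sessions run 60 s of baseline plus 420 s of
    interaction at 30 Hz frames. Class fractions per region default to the
    reported modulated proportions (PC: 10.7% excited / 28.5% inhibited;
    DN: 20.2% / 12.1%; ACC: 3.6% / 5.2%). Suppression windows are drawn from
    1-3 s, excitation from 2-4 s, at 50% fractional rate change. The complex
    spike pause on simple spikes is 40 ms.
    """

    arena_size: float = 480.0          # mm
    baseline_duration: float = 60.0    # s before target introduction
    interaction_duration: float = 420.0
    frame_rate: float = 30.0
    n_pc: int = 4
    n_dn: int = 8
    n_acc: int = 40
    class_fractions: dict = field(default_factory=lambda: {
        "PC_SS": (0.107, 0.285),   # (positive, negative); remainder ns
        "DN": (0.202, 0.121),
        "ACC": (0.036, 0.052),
    })
    baseline_rate_range: dict = field(default_factory=lambda: {
        "PC_SS": (50.0, 100.0),    # Hz
        "DN": (20.0, 60.0),
        "ACC": (0.2, 0.8),         # calcium event rate, Hz
    })
    modulation_amplitude: float = 0.5
    suppression_duration: tuple = (1.0, 3.0)   # s, PC and negative units
    excitation_duration: tuple = (2.0, 4.0)    # s, DN and positive units
    cs_rate: float = 1.0               # complex-spike rate, Hz
    cs_pause: float = 0.040            # s of SS silence after each CS
    coupling_strength: float = 0.5
    coupling_mode: str = "bouts_only"  # or "always"
    calcium_rise: float = 0.050        # s (GCaMP6f-like kernel)
    calcium_decay: float = 0.400
    noise_sd: float = 0.1
    n_bouts: int = 22
    bout_duration: tuple = (2.0, 5.0)
    min_gap: float = 8.0               # s between scheduled bouts
    approach_time: float = 0.4         # s for the target's closing ramp
    contact_distance: float = 12.0     # mm nose-to-body during a bout
    offbout_distance: tuple = (110.0, 230.0)
    mean_speed: float = 80.0           # mm/s subject OU speed scale
    speed_tau: float = 1.0             # s velocity relaxation time
    bout_slowdown: float = 0.4         # speed multiplier inside bouts
    wall_margin: float = 60.0          # mm subject keeps from the walls
    seed: int = 0

    def __post_init__(self) -> None:
        for region, (p, n) in self.class_fractions.items():
            if p < 0 or n < 0 or p + n > 1:
                raise ValueError(f"class fractions for {region} must sum to <= 1")
        for name in ("baseline_duration", "interaction_duration", "frame_rate",
                     "modulation_amplitude", "calcium_rise", "calcium_decay"):
            if getattr(self, name) <= 0 and name != "modulation_amplitude":
                raise ValueError(f"{name} must be positive")
        if self.coupling_mode not in ("bouts_only", "always"):
            raise ValueError("coupling_mode must be 'bouts_only' or 'always'")

    @property
    def session_duration(self) -> float:
        return self.baseline_duration + self.interaction_duration


@dataclass
class UnitTruth:
    unit_id: str
    unit_class: str
    label: str
    amplitude: float
    baseline_rate: float
    windows: np.ndarray  # (n, 2) frame intervals of the planted response
    coupling_gain: float = 0.0


@dataclass
class GroundTruth:
    """Everything the generator decided, for recovery tests."""

    bout_intervals: np.ndarray
    units: list[UnitTruth]
    pair_gains: dict  # (cb_unit, acc_neuron) -> planted gain product
    seed: int

    def labels(self, unit_class: str | None = None) -> dict[str, str]:
        return {u.unit_id: u.label for u in self.units
                if unit_class is None or u.unit_class == unit_class}

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "bout_intervals": np.asarray(self.bout_intervals).tolist(),
            "units": [
                {**{k: v for k, v in asdict(u).items() if k != "windows"},
                 "windows": np.asarray(u.windows).tolist()}
                for u in self.units
            ],
            "pair_gains": {f"{a}|{b}": g for (a, b), g in self.pair_gains.items()},
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------- behavior


def schedule_bouts(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Plant non-overlapping bout intervals (frames) in the interaction period."""
    if config.n_bouts == 0:
        return np.empty((0, 2), int)
    durs = rng.uniform(*config.bout_duration, size=config.n_bouts)
    start = config.baseline_duration + config.min_gap
    end = config.session_duration - config.min_gap
    slack = (end - start) - durs.sum() - (config.n_bouts - 1) * config.min_gap
    if slack < 0:
        raise ValueError(
            f"session too short to place {config.n_bouts} bouts: need "
            f"{-slack:.1f} s more interaction time"
        )
    extra = rng.dirichlet(np.ones(config.n_bouts + 1)) * slack
    onsets, t = [], start
    for i, d in enumerate(durs):
        t += extra[i]
        onsets.append(t)
        t += d + config.min_gap
    onsets = np.array(onsets)
    f0 = np.round(onsets * config.frame_rate).astype(int)
    f1 = np.round((onsets + durs) * config.frame_rate).astype(int)
    return np.stack([f0, f1], axis=1)


def _ou_series(n: int, dt: float, tau: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, mean 0, SD ``sd``."""
    a = np.exp(-dt / tau)
    noise = rng.standard_normal(n) * sd * np.sqrt(1 - a * a)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i]
    return x


def simulate_behavior(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[SessionTimeline, PositionSeries, BoutSet]:
    """Generate tracks for subject and target plus the planted bout schedule.

    The subject walks the arena with OU-smoothed velocity (reflecting walls,
    kept ``wall_margin`` mm inside); its speed drops by ``bout_slowdown``
    during bouts, as subjects do on interaction. The target sits at a
    scripted nose-to-body distance: well above the proximity threshold off
    bout, ramping to ``contact_distance`` over ``approach_time`` before each
    planted onset. Off-bout the distance floor (110 mm) guarantees no frame
    can be flagged at the default 20 mm threshold.
    """
    timeline = SessionTimeline.regular(config.session_duration, config.frame_rate)
    n = timeline.n_frames
    dt = 1.0 / config.frame_rate
    intervals = schedule_bouts(config, rng)
    bout_ind = np.zeros(n, bool)
    for a, b in intervals:
        bout_ind[a:b] = True

    # subject body: OU velocity random walk, reflecting at the margin box
    lo, hi = config.wall_margin, config.arena_size - config.wall_margin
    vsd = config.mean_speed / np.sqrt(2)  # per-axis SD -> |v| ~ mean_speed
    vx = _ou_series(n, dt, config.speed_tau, vsd, rng)
    vy = _ou_series(n, dt, config.speed_tau, vsd, rng)
    slow = np.where(bout_ind, config.bout_slowdown, 1.0)
    body = np.empty((n, 2))
    body[0] = rng.uniform(lo, hi, size=2)
    for i in range(1, n):
        step = np.array([vx[i], vy[i]]) * slow[i] * dt
        p = body[i - 1] + step
        for ax in range(2):  # reflect at the margin box
            if p[ax] < lo:
                p[ax] = 2 * lo - p[ax]
            elif p[ax] > hi:
                p[ax] = 2 * hi - p[ax]
        body[i] = p

    # heading from displacement, frozen when nearly stationary
    disp = np.vstack([body[1] - body[0], np.diff(body, axis=0)])
    heading = np.arctan2(disp[:, 1], disp[:, 0])
    speed = np.linalg.norm(disp, axis=1) / dt
    for i in range(1, n):
        if speed[i] < 5.0:
            heading[i] = heading[i - 1]
    hvec = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    nose = body + 30.0 * hvec
    led = body - 10.0 * hvec

    # scripted nose-to-target-body distance profile
    dist = _ou_series(n, dt, 5.0, 25.0, rng) + np.mean(config.offbout_distance)
    dist = np.clip(dist, *config.offbout_distance)
    ramp_f = max(1, int(round(config.approach_time * config.frame_rate)))
    jitter = 3.0 * np.sin(2 * np.pi * np.arange(n) * dt / 1.7)
    for a, b in intervals:
        dist[a:b] = config.contact_distance + jitter[a:b]
        r0 = max(0, a - ramp_f)
        dist[r0:a] = np.linspace(dist[r0], config.contact_distance, a - r0,
                                 endpoint=False)
        r1 = min(n, b + ramp_f)
        dist[b:r1] = np.linspace(config.contact_distance,
                                 np.mean(config.offbout_distance), r1 - b,
                                 endpoint=False)

    theta = np.cumsum(_ou_series(n, dt, 3.0, 0.8, rng) * dt)  # slow offset angle
    off = np.stack([np.cos(theta), np.sin(theta)], axis=1) * dist[:, None]
    tgt_body = nose + off
    # flip offset components whose endpoint leaves the arena (preserves |offset|)
    for ax in range(2):
        bad = (tgt_body[:, ax] < 0) | (tgt_body[:, ax] > config.arena_size)
        tgt_body[bad, ax] = nose[bad, ax] - off[bad, ax]

    # target oriented broadside to the subject: the body centroid is always
    # the nearest part, so contact distance is controlled by the profile alone
    tgt_heading = theta + np.pi / 2
    tvec = np.stack([np.cos(tgt_heading), np.sin(tgt_heading)], axis=1)
    tgt_nose = np.clip(tgt_body + 30.0 * tvec, 0, config.arena_size)
    tgt_tail = np.clip(tgt_body - 35.0 * tvec, 0, config.arena_size)

    pos = PositionSeries(
        points={
            "subj_nose": nose, "subj_body": body, "led": led,
            "tgt_nose": tgt_nose, "tgt_body": tgt_body, "tgt_tail": tgt_tail,
        },
        mask=np.ones(n, bool),
    )
    truth = BoutSet(intervals, ["nose-body"] * intervals.shape[0], n)
    return timeline, pos, truth


# ------------------------------------------------------------------ spikes


def _draw_windows(
    intervals: np.ndarray, dur_range: tuple, frame_rate: float, n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One response window per bout onset, with a per-bout drawn duration."""
    if intervals.size == 0:
        return np.empty((0, 2), int)
    durs = rng.uniform(*dur_range, size=intervals.shape[0])
    a = intervals[:, 0]
    b = np.minimum(n_frames, a + np.round(durs * frame_rate).astype(int))
    return np.stack([a, b], axis=1)


def modulated_rate(
    baseline: float, label: str, windows: np.ndarray, amplitude: float, n_frames: int,
) -> np.ndarray:
    """Per-frame rate: baseline, scaled by (1 ± amplitude) inside windows."""
    rate = np.full(n_frames, float(baseline))
    factor = {"positive": 1 + amplitude, "negative": 1 - amplitude, "ns": 1.0}[label]
    for a, b in windows:
        rate[a:b] = baseline * factor
    return np.clip(rate, 0.0, None)


def social_latent(
    intervals: np.ndarray, n_frames: int, frame_rate: float, mode: str,
    rng: np.random.Generator, tau: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared latent for cross-region coupling: (unit-SD OU path, gate).

    In ``bouts_only`` mode the gate is true only on bout frames (the coupled
    variability exists only while the animals interact); in ``always`` mode
    it spans the whole session.
    """
    u = _ou_series(n_frames, 1.0 / frame_rate, tau, 1.0, rng)
    gate = np.ones(n_frames, bool)
    if mode == "bouts_only":
        gate = np.zeros(n_frames, bool)
        for a, b in intervals:
            gate[a:b] = True
    return u, gate


def apply_latent(rate: np.ndarray, gain: float, latent: np.ndarray,
                 gate: np.ndarray) -> np.ndarray:
    """Multiplicative coupling ``rate * (1 + g*u)`` on gated frames only.

    The multiplier is symmetric around 1 (median and mean both 1 up to the
    rare clip at 0), so coupling adds shared variability without shifting
    either the mean rate or the rank distribution; off-gate frames are left
    untouched.
    """
    if gain == 0:
        return rate
    mult = np.where(gate, np.clip(1.0 + gain * latent, 0.0, None), 1.0)
    return rate * mult


def spikes_from_rate(
    rate: np.ndarray, timeline: SessionTimeline, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson times from a piecewise-constant frame rate."""
    dt = np.diff(timeline.bin_edges)
    counts = rng.poisson(rate * dt)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(timeline.t, counts)
    widths = np.repeat(dt, counts)
    return np.sort(starts + widths * rng.uniform(size=total))


def _assign_labels(n: int, fractions: tuple, rng: np.random.Generator) -> list[str]:
    """Deterministic counts (rounded) from class fractions, shuffled order."""
    n_pos = int(round(fractions[0] * n))
    n_neg = int(round(fractions[1] * n))
    n_pos, n_neg = min(n_pos, n), min(n_neg, n - n_pos)
    labels = (["positive"] * n_pos + ["negative"] * n_neg
              + ["ns"] * (n - n_pos - n_neg))
    rng.shuffle(labels)
    return labels


def simulate_spike_trains(
    bouts: BoutSet,
    timeline: SessionTimeline,
    config: SynthConfig,
    rng: np.random.Generator,
    unit_class: str = "DN",
    n_units: int | None = None,
    labels: list[str] | None = None,
    latent: tuple[np.ndarray, np.ndarray] | None = None,
    latent_gains: dict[str, float] | None = None,
    cs_mode: bool | None = None,
) -> tuple[list[SpikeTrain], list[UnitTruth]]:
    """Poisson spike trains with bout-locked modulation and known truth.

    Negative units scale their baseline by (1 - amplitude) for a drawn
    suppression window (1-3 s) after each bout onset; positive units elevate
    analogously over 2-4 s; ns units are homogeneous. For Purkinje cells
    (``cs_mode``) a low-rate complex-spike train is added and the simple
    spikes are silenced for ``cs_pause`` (default 40 ms) after each CS.
    """
    if n_units is None:
        n_units = config.n_pc if unit_class == "PC_SS" else config.n_dn
    if labels is None:
        labels = _assign_labels(n_units, config.class_fractions[unit_class], rng)
    if cs_mode is None:
        cs_mode = unit_class == "PC_SS"
    lo, hi = config.baseline_rate_range[unit_class]
    if lo <= 0:
        raise ValueError("baseline rates must be positive")
    n = timeline.n_frames
    trains: list[SpikeTrain] = []
    truths: list[UnitTruth] = []
    prefix = {"PC_SS": "pc", "DN": "dn"}.get(unit_class, unit_class.lower())
    for i, label in enumerate(labels):
        uid = f"{prefix}{i:03d}"
        base = rng.uniform(lo, hi)
        dur_range = (config.excitation_duration if label == "positive"
                     else config.suppression_duration)
        windows = (_draw_windows(bouts.intervals, dur_range, timeline.frame_rate,
                                 n, rng)
                   if label != "ns" else np.empty((0, 2), int))
        amp = config.modulation_amplitude if label != "ns" else 0.0
        rate = modulated_rate(base, label, windows, amp, n)
        gain = (latent_gains or {}).get(uid, 0.0)
        if latent is not None and gain:
            rate = apply_latent(rate, gain, *latent)
        times = spikes_from_rate(rate, timeline, rng)
        if cs_mode:
            cs_rate = np.full(n, config.cs_rate)
            cs_times = spikes_from_rate(cs_rate, timeline, rng)
            if cs_times.size:
                after = cs_times[np.searchsorted(cs_times, times, "right") - 1]
                keep = (times - after > config.cs_pause) | (times < cs_times[0])
                times = times[keep]
            trains.append(SpikeTrain(f"{uid}_cs", "PC_CS", cs_times))
        # amplitude 0 means no modulation was planted: truth label is ns
        truths.append(UnitTruth(uid, unit_class, label if amp > 0 else "ns",
                                amp, base, windows, gain))
        trains.append(SpikeTrain(uid, unit_class, times))
    return trains, truths


# ----------------------------------------------------------------- calcium


def calcium_kernel(
    rise: float, decay: float, frame_rate: float, length_s: float = 3.0
) -> np.ndarray:
    """Causal double-exponential kernel, peak-normalized to 1.

    k(t) = exp(-t/decay) - exp(-t/rise); the peak sits at
    t* = rise*decay/(decay-rise) * ln(decay/rise).
    """
    if decay <= rise:
        raise ValueError("calcium decay must exceed rise time")
    t = np.arange(0, length_s, 1.0 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def simulate_calcium(
    latent_rates: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
    timeline: SessionTimeline | None = None,
) -> np.ndarray:
    """Trace matrix from per-neuron event rates (Hz), neurons x frames.

    Poisson events drawn per frame are convolved with the causal
    double-exponential kernel and Gaussian noise of SD ``noise_sd`` is added.
    """
    rates = np.atleast_2d(np.asarray(latent_rates, float))
    dt = 1.0 / config.frame_rate
    kernel = calcium_kernel(config.calcium_rise, config.calcium_decay,
                            config.frame_rate)
    events = rng.poisson(rates * dt).astype(float)
    traces = np.empty_like(events)
    for i in range(events.shape[0]):
        traces[i] = np.convolve(events[i], kernel)[: events.shape[1]]
    if config.noise_sd > 0:
        traces += rng.normal(0, config.noise_sd, size=traces.shape)
    return traces


def acc_latent_rates(
    bouts: BoutSet,
    timeline: SessionTimeline,
    config: SynthConfig,
    rng: np.random.Generator,
    n_neurons: int | None = None,
    labels: list[str] | None = None,
    latent: tuple[np.ndarray, np.ndarray] | None = None,
    latent_gains: dict[str, float] | None = None,
) -> tuple[np.ndarray, list[UnitTruth]]:
    """Per-neuron calcium event rates with bout-locked modulation + truth."""
    if n_neurons is None:
        n_neurons = config.n_acc
    if labels is None:
        labels = _assign_labels(n_neurons, config.class_fractions["ACC"], rng)
    lo, hi = config.baseline_rate_range["ACC"]
    n = timeline.n_frames
    rates = np.empty((n_neurons, n))
    truths = []
    for i, label in enumerate(labels):
        uid = f"acc{i:03d}"
        base = rng.uniform(lo, hi)
        dur_range = (config.excitation_duration if label == "positive"
                     else config.suppression_duration)
        windows = (_draw_windows(bouts.intervals, dur_range, timeline.frame_rate,
                                 n, rng)
                   if label != "ns" else np.empty((0, 2), int))
        amp = config.modulation_amplitude if label != "ns" else 0.0
        rate = modulated_rate(base, label, windows, amp, n)
        gain = (latent_gains or {}).get(uid, 0.0)
        if latent is not None and gain:
            rate = apply_latent(rate, gain, *latent)
        rates[i] = rate
        truths.append(UnitTruth(uid, "ACC", label if amp > 0 else "ns",
                                amp, base, windows, gain))
    return rates, truths


# ----------------------------------------------------------------- session


@dataclass
class SyntheticSession:
    """Complete generated session plus its ground truth."""

    timeline: SessionTimeline
    positions: PositionSeries
    spike_trains: list[SpikeTrain]
    traces: np.ndarray        # ACC neurons x frames (raw, not z-scored)
    acc_ids: list[str]
    truth: GroundTruth


def simulate_session(config: SynthConfig | None = None,
                     seed: int | None = None) -> SyntheticSession:
    """Generate a full joint session from one seed.

    The seed fans out into named substreams (behavior / spikes / calcium /
    coupling) so each stage is independently reproducible. Coupling gains
    of +strength (positive units) and -strength (negative units) tie every
    modulated unit to one shared social latent; the planted per-pair gain is
    the product of the two units' gains.
    """
    config = config or SynthConfig()
    seed = config.seed if seed is None else seed
    rngs = substreams(seed, "behavior", "spikes", "calcium", "coupling")
    timeline, pos, bouts = simulate_behavior(config, rngs["behavior"])
    latent = social_latent(bouts.intervals, timeline.n_frames, config.frame_rate,
                           config.coupling_mode, rngs["coupling"])

    sign = {"positive": 1.0, "negative": -1.0, "ns": 0.0}
    g = config.coupling_strength
    spike_rng = rngs["spikes"]
    pc_labels = _assign_labels(config.n_pc, config.class_fractions["PC_SS"],
                               spike_rng)
    dn_labels = _assign_labels(config.n_dn, config.class_fractions["DN"],
                               spike_rng)
    pc_gains = {f"pc{i:03d}": g * sign[lab] for i, lab in enumerate(pc_labels)}
    dn_gains = {f"dn{i:03d}": g * sign[lab] for i, lab in enumerate(dn_labels)}
    pc_trains, pc_truth = simulate_spike_trains(
        bouts, timeline, config, spike_rng, "PC_SS", labels=pc_labels,
        latent=latent, latent_gains=pc_gains)
    dn_trains, dn_truth = simulate_spike_trains(
        bouts, timeline, config, spike_rng, "DN", labels=dn_labels,
        latent=latent, latent_gains=dn_gains)

    ca_rng = rngs["calcium"]
    acc_labels = _assign_labels(config.n_acc, config.class_fractions["ACC"], ca_rng)
    acc_gains = {f"acc{i:03d}": g * sign[lab] for i, lab in enumerate(acc_labels)}
    rates, acc_truth = acc_latent_rates(bouts, timeline, config, ca_rng,
                                        labels=acc_labels, latent=latent,
                                        latent_gains=acc_gains)
    traces = simulate_calcium(rates, config, ca_rng, timeline)

    units = pc_truth + dn_truth + acc_truth
    cb_ids = [u.unit_id for u in pc_truth + dn_truth]
    pair_gains = {
        (cb, acc): (pc_gains | dn_gains)[cb] * acc_gains[acc]
        for cb in cb_ids for acc in acc_gains
    }
    truth = GroundTruth(bouts.intervals, units, pair_gains, seed)
    return SyntheticSession(timeline, pos, pc_trains + dn_trains, traces,
                            [u.unit_id for u in acc_truth], truth)
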