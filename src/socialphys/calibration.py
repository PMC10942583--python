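"""Empirical calibration of the modulation classifier's false-positive rate.

Simulates homogeneous (unmodulated) Poisson units against a realistic bout
schedule, runs them through the full classification path — frame binning,
Gaussian smoothing, z-scoring, AUC, circular-shuffle null — and reports the
fraction labeled modulated per tail. Under a calibrated classifier that
fraction cannot exceed the per-tail criterion (0.025) beyond binomial noise.
"""

from __future__ import annotations

import numpy as np

from .behavior import BoutSet
from .core import AnalysisParams, SessionTimeline, substreams
from .modulation import classify_modulation
from .preprocess import SpikeTrain, bin_spikes, smooth_rate, zscore_series
from .synth import SynthConfig, schedule_bouts, spikes_from_rate


def null_false_positive_rate(
    n_units: int = 1000,
    rate_hz: float = 20.0,
    duration: float = 480.0,
    params: AnalysisParams | None = None,
    seed: int = 0,
    synth_config: SynthConfig | None = None,
) -> dict:
    """Per-tail empirical false-positive rate on unmodulated Poisson units.

    Each unit is a homogeneous Poisson train at ``rate_hz`` over ``duration``
    seconds, classified against a planted bout schedule (default: the
    generator's standard session, ~16% of frames interacting) that the units
    ignore by construction. Returns the fraction labeled positive and
    negative, plus binomial standard errors at the nominal per-tail level.
    """
    params = params or AnalysisParams()
    cfg = synth_config or SynthConfig()
    rngs = substreams(seed, "bouts", "spikes", "shuffles")
    timeline = SessionTimeline.regular(duration, cfg.frame_rate)
    intervals = schedule_bouts(cfg, rngs["bouts"])
    bouts = BoutSet(intervals, ["nose-body"] * intervals.shape[0],
                    timeline.n_frames)
    indicator = bouts.indicator
    rate = np.full(timeline.n_frames, rate_hz)

    n_pos = n_neg = 0
    for i in range(n_units):
        times = spikes_from_rate(rate, timeline, rngs["spikes"])
        train = SpikeTrain(f"null{i:04d}", "DN", times)
        z = zscore_series(smooth_rate(bin_spikes(train, timeline),
                                      params.kernel_sigma, params.bin_width))
        m = classify_modulation(z.values, indicator, params, rngs["shuffles"],
                                timeline.frame_rate, unit_id=train.unit_id)
        n_pos += m.label == "positive"
        n_neg += m.label == "negative"
    se = float(np.sqrt(params.alpha_per_tail * (1 - params.alpha_per_tail)
                       / n_units))
    return {
        "n_units": n_units,
        "fraction_positive": n_pos / n_units,
        "fraction_negative": n_neg / n_units,
        "alpha_per_tail": params.alpha_per_tail,
        "binomial_se": se,
        "interaction_fraction": float(indicator.mean()),
    }
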