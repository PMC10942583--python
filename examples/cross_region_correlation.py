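"""Cerebellum-ACC pair correlations in social vs non-social epochs.

Computes Pearson r for every (cerebellar unit, ACC neuron) pair over the
full session and again over off-bout frames only (1 s pad around bouts),
with circular-shift surrogates for significance. With coupling delivered
during bouts, same-sign pairs out-correlate opposite-sign pairs — and the
difference collapses off-bout.
"""

import numpy as np

from socialphys import (AnalysisParams, TraceMatrix, bin_spikes,
                        build_epoch_mask, pair_correlation, simulate_session,
                        smooth_rate, zscore_series, zscore_traces)
from socialphys.behavior import BoutSet

session = simulate_session(seed=3)
params = AnalysisParams(n_shuffles=200)
timeline = session.timeline
bouts = BoutSet(session.truth.bout_intervals,
                ["nose-body"] * session.truth.bout_intervals.shape[0],
                timeline.n_frames)
truth = session.truth.labels()

rates = {t.unit_id: zscore_series(smooth_rate(
    bin_spikes(t, timeline), params.kernel_sigma, params.bin_width)).values
    for t in session.spike_trains if t.unit_class in ("PC_SS", "DN")}
ztr = zscore_traces(TraceMatrix(session.acc_ids, session.traces))

for mode in ("full", "offbout"):
    mask = build_epoch_mask(bouts, mode, timeline, pad=params.offbout_pad)
    same, opp = [], []
    for uid, rate in rates.items():
        for i, nid in enumerate(ztr.neuron_ids):
            if truth[uid] == "ns" or truth[nid] == "ns":
                continue
            r = pair_correlation(rate, ztr.values[i], mask)
            (same if truth[uid] == truth[nid] else opp).append(r)
    print(f"{mode:8s} median r same-sign {np.median(same):+.3f} "
          f"({len(same)} pairs), opposite-sign {np.median(opp):+.3f} "
          f"({len(opp)} pairs)")
# The same-sign vs opposite-sign gap in full mode reflects bout-locked
# co-modulation; its collapse off-bout shows the correlation is carried by
# social epochs, not intrinsic connectivity.
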