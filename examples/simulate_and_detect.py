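"""Generate a synthetic session and recover its interaction bouts.

Builds an 8-minute arena session (1 min baseline + 7 min with a target),
then runs proximity-based bout detection (nose within 20 mm of the target's
nose, body, or tail base) and compares against the planted schedule.
"""

import numpy as np

from socialphys import assemble_bouts, detect_interaction_frames, simulate_session

session = simulate_session(seed=1)
ind, tags = detect_interaction_frames(session.positions, threshold=20.0)
bouts = assemble_bouts(ind, session.timeline.frame_rate, tag_idx=tags)

truth = np.zeros(session.timeline.n_frames, bool)
for a, b in session.truth.bout_intervals:
    truth[a:b] = True
jaccard = (truth & bouts.indicator).sum() / (truth | bouts.indicator).sum()

print(f"planted bouts:  {session.truth.bout_intervals.shape[0]}")
print(f"detected bouts: {bouts.n_bouts}")
print(f"interaction time: {bouts.indicator.mean():.1%} of frames")
print(f"frame-level Jaccard vs truth: {jaccard:.3f}")
print("mean bout duration: "
      f"{bouts.durations_s(session.timeline).mean():.1f} s")
# Jaccard near 1 means detection recovered the planted schedule almost
# frame-for-frame; the ~15% interaction time matches a typical session.
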