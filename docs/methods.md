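# Methods

## Analysis model

All data streams share one frame clock at the imaging rate (nominally
30 Hz). Spike-train bin edges are the frame timestamps themselves, so the
"33 ms" bin is nominal and spike-rate frames align 1:1 with calcium frames
by construction. Rates are convolved with a unit-area Gaussian (σ = 100 ms,
truncated at ±4σ) and z-scored per unit over the whole session using the
population SD (divide by N). Zero-variance series are flagged degenerate
and excluded from downstream tests rather than raising.

Two padding modes exist for smoothing: `reflect` (default, for display and
standard analysis) and `wrap` (circular). With circular padding, smoothing
and z-scoring commute exactly with circular shifts — the property that
justifies building shuffle nulls by rotating the *preprocessed* activity
rather than re-preprocessing each rotation.

### Modulation classification

AUC is computed through the tie-corrected Mann–Whitney identity with
midranks, which is exact including ties. The null rotates the activity by
a uniform random shift in [min_shift, L − min_shift] frames
(min_shift = 10 s by default, large enough to break bout-locking despite
the ~0.3 s autocorrelation the smoothing kernel introduces). Because
rotating a series rotates its midranks, all shuffle AUCs are obtained by
gather-sums over a single rank computation — exact and fast enough for
1000-shuffle nulls over thousands of units. P-values use the add-one rule
p = (1 + #{null ≥ obs})/(1 + n_shuffles): valid under exchangeability and
never zero. The per-tail criterion is 0.025 (two-tailed 0.05). Units where
either class covers less than 1% of frames are returned ns with a
`low_coverage` flag instead of silently dropped. Shuffling rotates the
activity, not the indicator; the two are equivalent under rotation and the
choice is fixed for reproducibility.

### Pair correlation and surrogates

Pearson r is computed over usable frames only (full session, or off-bout
frames with a pad — default 1 s — removed around each bout to absorb the
1–4 s response tails of modulated units). Surrogates shift the intact
full-length calcium trace and apply the mask afterwards (shift-then-mask),
so surrogate segments carry the same within-epoch autocorrelation as the
observed trace. Only the calcium trace is shifted, not the spike rate.
Significance is two-sided at corr_alpha = 0.05 — the conventional level,
exposed in `AnalysisParams`. Z-scoring happens once on the full session and
is reused for both epoch modes; restricting to a mask changes r only
through frame selection, not through renormalization.

### Behavior

An interaction frame has the subject's nose within 20 mm of the target's
nose, body centroid, or tail base (point distances; the tag is the nearest
part). Runs of flagged frames separated by gaps < 0.5 s are merged and runs
shorter than 0.2 s dropped — values chosen to suppress single-frame
tracking jitter; the proximity rule itself carries the scientific content.
Speed and head angular speed come from the head-mounted LED: speed is the
centered-difference displacement over time; heading is the displacement
direction (a single LED carries no orientation, so displacement is the
proxy — an explicit design decision, not an inference from hardware), with
angular speed the wrapped heading change per unit time, reported as 0 below
5 mm/s where heading is undefined. Movement events use hysteresis
thresholds (onset crossing above `on_thresh` after ≥ 1 s below
`off_thresh`) so jitter around a single threshold cannot spawn events.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
mouse biomechanics. A session is 60 s of baseline plus 420 s of interaction
in a 480 × 480 mm arena at 30 Hz. Defaults and what they encode:

| parameter | default | rationale |
| --- | --- | --- |
| bout schedule | 22 bouts, 2–5 s, ≥8 s gaps | short sniffing-bout kinematics; ~16% of frames interacting |
| PC simple-spike baseline | 50–100 Hz | high-rate PC firing |
| DN baseline | 20–60 Hz | deep-nucleus range |
| ACC event rate | 0.2–0.8 Hz | sparse cortical calcium transients |
| modulation amplitude | 0.5 | 50% suppression/elevation |
| suppression window | 1–3 s per bout onset | PC inhibition kinetics |
| excitation window | 2–4 s per bout onset | DN excitation kinetics |
| CS rate / SS pause | 1 Hz / 40 ms | complex-spike pause QA signature |
| calcium kernel | 50 ms rise, 400 ms decay | GCaMP6f-like double exponential |
| class fractions | PC 10.7/28.5, DN 20.2/12.1, ACC 3.6/5.2 (%) | reported modulated proportions |

The subject walks with Ornstein–Uhlenbeck-smoothed velocity (mean speed
80 mm/s, 1 s relaxation), reflecting at a 60 mm wall margin, and slows to
40% speed during bouts. The target's nose-to-body distance is scripted:
110–230 mm off-bout (guaranteeing no spurious detection at the 20 mm
threshold), ramping to 12 mm over 0.4 s before each planted onset. The
target is oriented broadside so the body centroid is always the nearest
part; offset components that would leave the arena are sign-flipped, which
preserves the scripted distance exactly. Spikes are inhomogeneous Poisson
(frame-resolution piecewise-constant rate, uniform jitter within frames);
calcium is Poisson events convolved with the causal kernel plus Gaussian
noise (SD 0.1).

Cross-region coupling is one shared latent u(t) — a unit-SD OU path with
2 s timescale, gated to bout frames by default ("bouts_only") or running
throughout ("always") — applied multiplicatively as rate·(1 + g·u), with
g = +0.5 for positively and −0.5 for negatively modulated units. The
multiplier is symmetric around 1, so coupling adds shared variability
without shifting mean rates or rank distributions; the planted per-pair
coupling is the product of the two units' gains. Coupling a latent into
rates (rather than mixing traces) keeps modality-specific noise
independent.

One seed fans out into named substreams (behavior / spikes / calcium /
coupling; in the pipeline: synth / classify / correlate) so stages can be
regenerated independently and fixed seeds give byte-identical outputs
(fixed float formatting in CSV/JSON).

What the generator does *not* emulate: pose and body-outline geometry,
tracking dropouts and identity swaps, non-stationary baselines, bursting
and oscillatory spike statistics, calcium indicator saturation and
neuropil contamination, and realistic bout-rate differences between social
and object targets. Passing recovery tests therefore shows the analysis is
correct and calibrated under its own assumptions, not that those
assumptions hold in any particular recording.

## Problem sizes

Calibration and recovery checks run at full session length (480 s,
14 400 frames) with 1000-shuffle nulls: 1000 unmodulated units for null
calibration, 100 units per class for recovery, 1000 independent pairs for
correlation calibration plus 60 coupled pairs for power and 2 × 30 pairs
for the epoch-ablation comparison. Unit tests use a scaled-down 3-minute
session with a handful of units.

## Numerical choices and degenerate inputs

- Midranks make AUC exact under ties; brute-force pair enumeration is the
  test oracle.
- Add-one p-values bound the false-positive rate conservatively at finite
  shuffle counts.
- Gaussian kernel is normalized to unit sum after truncation, so constant
  inputs are preserved exactly and sums conserved to < 1e-6 for
  interior-supported input.
- Constant-on-mask series are excluded from correlation as degenerate,
  reported per pair, never silently.
- PETHs exclude (and count) events whose window exits the session; a
  single-event PETH reports SEM 0 with a flag.
- Circular shifts are `np.roll`; shift validity is 0 ≤ s < L.

## Known limitations

- Off-bout pad (1 s) is a default, not an inferred quantity; response tails
  longer than the pad leak social signal into "non-social" frames.
- Heading from LED displacement is undefined at rest; angular-speed
  statistics near zero speed are floor-imputed, which deflates
  rotation-event counts in very still animals.
- The confound test shuffles event *times*, preserving event count but not
  any clustering structure of real locomotion events.
- Object-interaction sessions are analytically identical to social ones
  here (same proximity rule against an object centroid); the package does
  not model object-specific behavior.
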