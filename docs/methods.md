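# Methods

This note documents the models and procedures implemented in `photoperant`,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not establish about real recordings.

## Task state machine

All timing lives on one master clock in seconds with t = 0 at session start.
The behavioral sync pulse is represented as an explicit `sync_offset_s`
applied once when a photometry file is loaded, so behavior and photometry
share a timebase.

Phase rules implemented by the simulator and enforced by the independent
replay checker (`events.check_contingency`):

- **Phase I (classical conditioning).** Tones of `tone_duration_s` (default
  5 s) separated by `intertrial_interval_s` (default 15 s); the spout is
  always accessible but a lick is rewarded only while the tone plays. Default
  8 training days, two tests per day, 5–10 trials per test (drawn uniformly,
  emulating the experimenter-adjusted trial counts used to avoid satiation).
- **Phase II (free operant).** No tone; tests last `test_duration_s`
  (default 300 s). A lever press outside an open trial opens a trial of
  `trial_duration_s` (default 10 s) and makes the spout available for
  `reward_window_s` (default 5 s). A press inside an open trial is logged as
  an additional press of that trial and does **not** open a new trial or
  re-arm the spout; whether the physical rig re-armed is not observable from
  published descriptions, so the choice is held consistently by the
  generator, the segmenter, and the replay checker (and is configurable
  through `trial_duration_s`). Default 6 days.
- **Phase III (cued operant).** Tones as in Phase I; only a press inside the
  tone window opens the spout for `reward_window_s`. Default 5 days.

All windows are half-open `[start, end)`; a lick exactly at tone offset is
outside the cue. Rewards are logged at the rewarded lick's own timestamp, so
"rewarded lick" is operationalized downstream as a lick whose timestamp
matches a `reward_delivery` within 1 ms rather than by re-deriving spout
state — robust to truncated logs.

### Outcome classes

A trial is **rewarded** iff it contains at least one rewarded lick.
Otherwise: Phase III trials with zero presses are **no_presses**; Phase I
trials with zero licks are **no_licks**; everything else (licks outside the
cue, presses without consumption) is **non_rewarded**. Classification is
deterministic and exhaustive; on noise-free synthetic sessions it matches
the simulator's ground truth on every trial by construction, which the
closed-loop tests verify.

## Virtual learning mouse

The agent's expected action latency relaxes exponentially,

    latency(day) = asymptote + (init − asymptote) · exp(−(day−1)/τ),

with engagement probability rising on the same time constant (τ default
2 days). Defaults — initial latency 8 s falling to 1.5 s, engagement 0.4
rising to 0.95 — were chosen so that a default cohort reproduces the
qualitative training course of this task family: early Phase I tone-licks
often miss the 5 s cue (non-rewarded), success rates and lick counts climb
over days, and Phase III begins near-proficient. Individual latencies are
log-normal around the schedule with CV 0.3 (published learning curves
constrain trends, not distributions; log-normal keeps latencies positive
with a realistic right tail). Licking is a regular 8 Hz train lasting 2 s —
the center of the murine lick-rate range — because only counts and onsets
matter downstream. Press forces are uniform in an arbitrary 10–40 range.

## Generative photometry model

The calcium-dependent channel is

    F465(t) = B465 · bleach(t) · (1 + s(t) + a(t) + ε(t)),

with `bleach(t) = exp(−t/τ_bleach)` (default τ = 3000 s), `s(t)` the sum of
transient kernels and consumption dips, `a(t)` a sparse shared motion
artifact, and ε white noise (SD 0.003 ΔF/F). The isosbestic channel carries
the same bleach, the same `a(t)` scaled by `artifact_gain_405`, and
independent noise — but no transients, which is the defining property of the
isosbestic wavelength.

Design choices worth stating explicitly:

- **Transients are multiplicative on the baseline** and their kernels
  `K(t) ∝ (1 − e^{−t/τ_rise}) e^{−t/τ_decay}` (defaults 0.1 s / 0.8 s, a
  fast-indicator regime) are normalized to unit peak, so a ground-truth
  amplitude *A* is exactly the peak ΔF/F contribution — making recovery
  slopes directly interpretable.
- **The artifact is a shared fractional modulation**, not an additive raw
  offset. Motion changes coupling efficiency, which scales each channel's
  own fluorescence; it also makes the unit-gain subtraction exact after
  ratio normalization in the noise-free case, which is the property the
  artifact-rejection tests exercise.
- **Amplitudes follow trial outcome** (defaults 0.08 rewarded / 0.04
  non-rewarded ΔF/F, both well above the 2-SD detection threshold at default
  noise), plus an optional per-day ramp (`amp_day_ramp`) for
  amplitude-learning regimes. A **consumption dip** (−0.015 ΔF/F, rise
  0.5 s, decay 2 s) follows each rewarded lick-bout onset with a 0.5 s
  delay, emulating the signal depression during reward consumption while
  leaving the bout-onset transient peak essentially unperturbed.
- The sampling rate is configurable (default 100 Hz — typical for this
  modality; acquisition-rate metadata is written into every file). If the
  rate resolves the rise time with fewer than two samples a warning is
  recorded in the recording's provenance.

## Signal processing

- **Normalization** is `(F − F₀)/F₀` with F₀ a centered rolling mean whose
  window shrinks at the edges. The window length (default 30 s) must sit
  between the transient timescale (~1 s) and the bleaching timescale
  (~1000 s); 30 s leaves single transients attenuated by only ~3–4% (a
  transient's own mass inflates its local baseline by ∫K/window) while
  tracking slow drift. The ratio form makes the output invariant to any
  positive gain on raw F. A non-positive baseline is an error: raw
  fluorescence must be positive.
- **Subtraction** acts on the normalized channels (the per-channel ratio
  normalization is what makes the two channels commensurate); unit gain is
  the default, with a least-squares fitted gain available for rigs with
  unmatched channels.
- **Peak events**: the subtracted trace is denoised with a short Gaussian
  kernel (σ = 0.05 s, half the default rise time) and every contiguous
  excursion above `2 × SD` contributes one event at its maximum. The SD is
  the **whole-session** standard deviation of the *unsmoothed* subtracted
  trace (a MAD-based robust option exists). Computing the threshold on the
  unsmoothed trace while scanning the denoised one is what makes a
  zero-transient recording yield exactly zero events — sample-to-sample
  noise is suppressed by ~4× by the smoothing while transients pass almost
  untouched — reproducing the flat-trace regime seen under anesthesia.
  Note the excursion rule reports two transients as one event if the trace
  never falls below threshold between them; at default parameters this
  affects presses and licks closer than ~1 s and is the main source of the
  few-percent miss rate in recovery tests.
- **Linking** attributes each peak to the nearest lever press or lick-bout
  onset within `[event, event + 2 s)` (the same 2 s used for windowed
  amplitude quantification), one peak per event, nearest-lag first, earlier
  event winning exact ties. A lick-bout onset is a lick preceded by ≥ 1 s
  without licks (configurable; the bout concept is standard but thresholds
  vary across labs).
- **Peri-event matrices** use nearest-sample extraction on the recording's
  own grid (no interpolation); rows whose window leaves the recording are
  kept, NaN-padded, and flagged incomplete rather than silently clipped.
- **SEM conventions**: cohort summaries use n = number of animals;
  within-session tables use n = trials; each table records its n.

## Tracking

Pose tables use the common two-header-row export layout in image coordinates
(origin top-left, y down; configurable by flipping the geometry). Frames
below the confidence threshold (default 0.6) are masked per part, never
interpolated; occupancy maps are normalized over unmasked frames only, and
distance series leave masked frames missing. The calcium–distance
correlation is rank-based by default and its p-value comes from a
circular-shift null (minimum shift 1 s), which preserves autocorrelation
that an i.i.d. shuffle would destroy. A constant distance yields an
explicitly undefined correlation, not zero. The default anchoring body part
is the head.

## Validation experiments and their scale

The test suite and `scripts/acceptance.py` run these experiments end to end
(sizes chosen to give stable statistics on one core in seconds):

- contingency replay over 50 sessions per phase (all training days cycled);
- closed-loop outcome classification over 45 sessions;
- 1,000 random short arrays against a nested-loop rolling-mean reference
  (agreement to 1e−10 relative);
- artifact rejection on a mid-training session, exactly (noise off) and by
  artifact correlation over 20 noise seeds;
- transient recovery over 20 free-operant sessions (~330 ground-truth
  transients): detection-and-correct-link rate ≥ 90%, detected-vs-generative
  amplitude slope within [0.85, 1.15];
- outcome-contrast recovery with a 3:1 rewarded:non-rewarded amplitude ratio
  over 10 mid-training classical-conditioning sessions. The quantification
  window is the 2 s from each trial's consumption-bout onset: under the
  Phase I contingency a non-rewarded bout necessarily lies outside the tone,
  so a tone-anchored window cannot contain that group's transient; anchoring
  at the bout onset measures both groups at their event, and for rewarded
  trials of a trained agent it coincides with the first 2 s of the tone;
- learning-curve recovery over an 8-mouse cohort (Spearman ρ of day-mean
  latencies), and a constant-amplitude proficient-cohort regime in Phase III
  whose amplitude-vs-day OLS slope must have a confidence interval
  containing zero — note this regime fixes *both* equal amplitudes across
  outcomes and a proficient agent, because an outcome-dependent amplitude
  combined with a shifting outcome mix would itself create a day trend;
- the anesthesia regime (transients off, artifacts and noise on): zero peak
  events and a flat tone-aligned mean. "Flat" is operationalized as no bin
  of the group mean reaching the peak-event criterion and only a
  chance-level fraction of bins beyond 2 SEM — a literal "every bin within
  2 SEM" would fail for any finite cohort by construction;
- byte-level determinism of a full pipeline rerun under a fixed seed.

## What the synthetic data does not capture

The generator reproduces the statistical structure the analysis assumes —
event-locked transients with outcome-dependent amplitude, consumption
depression, shared fractional artifacts, bleaching, white noise — but not
hemodynamic contamination, indicator nonlinearity or saturation, pH drift,
correlated (pink) noise, chewing/licking artifacts that differ between
wavelengths, or pose-estimation failure modes such as identity swaps.
Passing recovery tests therefore establishes that the pipeline is correct
under its stated model, not that the model exhausts real-data pathology.
Statistical inference on the resulting tables (ANOVA, post hoc tests) is
deliberately out of scope: the pipeline emits tidy per-trial/per-test/per-day
tables ready for any stats package.
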