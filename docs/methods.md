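# Methods

This note documents the models, parameter choices, and numerical
conventions behind `axonstate`, and what the synthetic test bed does and
does not establish about real recordings.

## The synthetic session generator

The generator produces sessions with the statistical structure the
analyses assume, with known ground truth, so every downstream stage can
be validated against a known answer.

**Behavioral-state process.** A semi-Markov process at the video rate
(30 Hz) alternates still intervals with movement bouts.  Still intervals
last at least `min_gap_s` (default 1.2 s) plus an exponential tail
(mean 8 s), so every bout is flanked by more than 1 s of stillness and
the event detector's gating can in principle recover all bouts.  Bout
kind is drawn from per-kind rates (defaults 0.05/s twitch, 0.03/s whisk,
0.012/s walk per second of still time); durations are uniform within
twitch (0.1–0.45 s), whisk (1.2–6 s), and walk (2.2–6 s) bounds.  The
field's literature does not pin these distributions; uniform durations
within the stated bounds are a deliberate simplification — sufficient
for testing the gating logic, not a model of mouse behavior.  A walk
bout is always embedded in a whisk bout that starts 0.5–5 s before walk
onset and persists 1–3 s after walk offset, reproducing the
whisking-leads-walking timing relation.  All times snap to the video
frame grid.  A `script` argument bypasses the random draw for exactness
tests; scripted bouts closer together than the minimum gap are re-spaced.

**Behavioral channels.** Wheel speed is ~0 when not walking and a
per-bout level of 3.5–6 cm/s during walk frames, so the 2.5 cm/s
threshold crossing aligns with the bout to within one frame.  Whisker-pad
MEI has baseline 0.05 and a per-bout level of 0.45–0.9; snout and jaw MEI
leak from the whisker trace (gain 0.5) with rare solo transients
(0.02/s) mimicking movements localized to one facial region; full-face
MEI is a weighted mixture.  Pupil diameter is the state drive passed
through a causal first-order lag with a 4 s time constant — the pupil
*lags* facial movement, as in real arousal data.  `behavior_noise_sd`
scales all behavioral jitter; 0 gives crisp, exactly recoverable traces.

**Fluorescence.** Per-axon drive is
`common_gain · drive_common + drive_private`, rectified at zero.  The
common drive is the state amplitude (still 0, twitch 0.8, whisk 1.0,
walk 1.3); after 1 s of sustained movement it is attenuated by
`1 − sustain_frac`, mimicking sustained (cholinergic-like,
`sustain_frac → 1`) versus transient (noradrenergic-like,
`sustain_frac → 0`) response profiles.  Private drives are Gaussian
noise low-passed at 0.5 Hz and scaled to `private_sd`; `planted_pairs`
adds a shared private component to chosen axon pairs.  The drive is
convolved with a difference-of-exponentials indicator kernel
(rise 0.15 s, decay 1.5 s by default, normalized to unit peak, applied
with the sample interval so that a unit-area impulse yields the
unit-peak kernel and a sustained unit drive settles near the kernel
integral — this keeps dF/F amplitudes of order 1 and commensurate with
`noise_sd`).  Traces are sampled at the imaging frame rate (10–30 Hz)
and embedded in a raw fluorescence scale
`F = baseline · (1 + gain · activity + noise)` with per-object baseline
and gain, so dF/F is something the preprocessing stage must actually
recover.  `noise_highpass_hz` optionally shapes the imaging noise above
a cutoff (used to emulate the same-axon frequency-limit condition).

**Control populations.** Same-axon pairs are two traces rendered from
one drive with independent noise, placed in one ROI (distance 0).  Blebs
are constant plus noise.  mCherry objects are constant plus one shared
low-frequency artifact trace scaled by per-object gains drawn from
N(0, 0.05) — near zero and signed, so ordinary and partial correlations
agree, as an activity-independent fluorophore should behave.

**What the generator does not emulate:** realistic bout-duration and
inter-bout statistics, eye movements, neuropil contamination, bleaching,
z-drift, frame-registration artifacts, spiking-level indicator
nonlinearity, or heterogeneous per-axon kinetics.  Passing tests
therefore certify the *analysis machinery* — detection exactness,
estimator calibration, decomposition behavior under known coupling — not
the biology of any particular recording.

## Event detection

Whisker events are maximal supra-threshold runs of the session-normalized
(min-max) whisker MEI at threshold 0.20: runs < 0.5 s are twitches,
runs > 1 s are whisk bouts, runs of 0.5–1 s are classified as neither
(the band is left undefined by convention) but still count as movement
for gating.  Walk bouts are runs of wheel speed > 2.5 cm/s lasting
≥ 2 s, detected independently, so walk and whisk events may overlap.
Every retained event needs ≥ 1 s of stillness before and after; by
default each kind gates on its own variable (whisker MEI for
twitch/whisk, speed for walk), and `strict=True` gates all kinds on
joint stillness of both.  There is no hysteresis — a single threshold
defines runs.  MEI sample *i* carries the timestamp of frame *i+1*
(energy is attributed to the frame where the change is observed).  Runs
touching the recording edges cannot have their gate verified and are
dropped.

## Preprocessing

Traces are linearly interpolated to a uniform 100 Hz grid (indicator
bandwidth is far below the input Nyquist, so interpolation error is
negligible) and low-pass filtered at 10 Hz with a zero-phase
forward-backward Butterworth of order 3 — zero-phase so event-aligned
timing is preserved.  Non-finite gaps up to 1 s are interpolated; longer
gaps are an error.  The SNR criterion is
`log(maxP[0.05–0.5 Hz] / meanP[1–3 Hz]) ≥ log 20` on a Welch estimate
with 60 s windows at 50% overlap (the estimator is a package choice).
The threshold is interpreted as log-ratio ≥ log 20, equivalently
ratio ≥ 20; a `log_scale` flag switches to comparing the raw ratio.
dF/F uses the session median as baseline.  Population statistics use
per-trace z-scores so large or bright objects do not dominate averages.
All correlation analyses are preceded by a zero-phase 1 Hz Butterworth
low-pass: the same-axon coherence limit (below) shows the indicator
carries essentially no usable information above ~1 Hz.

## Event-aligned statistics

Responsiveness compares mean dF/F in the second after event onset with
the second before, per (object, event), using a Welch t statistic.  A
plain t-test on autocorrelated calcium samples is anti-conservative, so
significance is assessed against the circular-shift shuffle null of the
same statistic: each object's trace is shifted by a uniform random
offset of at least 10 s (preserving autocorrelation), half of the
`n_shuffles` draws define the per-object 1−α threshold, and the other
half are held out as the null distribution of responding fractions.
This keeps the false-positive rate at the nominal α (verified at
α = 0.01 with 1000 shuffles); parametric Welch p-values are reported
alongside for reference.  Confidence bands on aligned means are
percentile bootstrap over events (1000 resamples).  Duration
stratification uses half-open bins [1,2), [2,3), [3,4) and (≥5) s,
leaving 4–5 s unassigned.  Display baselines (mean of the −2…−1 s
window) are subtracted for plots only, never for statistics.

**Sustainedness and indicator kinetics.** The sustainedness index is the
mean response 2–3 s after onset divided by the peak.  With a slow
indicator (decay 1.5 s) the index is biased upward as an estimator of
the underlying drive's sustained fraction: the step response has not
saturated when the transient peaks, and the decay tail bleeds into the
late window (analytically, a drive attenuated to fraction *s* after 1 s
yields an index near `s + 0.2(1−s)` … 0.8-ish depending on *s*).
Recovery of the generator's `sustain_frac` within ±0.05 is therefore
verified on noiseless sessions with fast kinetics (rise 0.05 s, decay
0.2 s), which isolates the estimator from kinetics bias; default-kernel
sessions verify the sustained-versus-transient *ordering*.  The same
consideration applies to the cross-correlation peak lag: with a slow
decay the peak sits near 1 s even when the onset latency is ~150 ms, so
the kernel-timing check uses a fast-decay configuration.  Real
sustained/transient contrasts measured on slow-indicator data embed this
bias, which is worth remembering when comparing printed percentages.

## Spectral analysis

Coherence is magnitude-squared coherence with 2 min Hamming windows at
98% overlap.  Windows this heavily overlapped are strongly correlated,
so confidence is reported exclusively through the shuffle control
(95th percentile of coherence against circularly shifted partners),
never through analytic degrees-of-freedom formulas.  Per-window
detrending is constant (mean removal).  Cross-correlation is normalized,
restricted to ±3 s, computed after the 1 Hz low-pass, with the sign
convention "positive lag = x lags y" recorded in the result.  The
same-axon coherence limit is the first frequency above 0.05 Hz where a
pair's coherence falls below 0.5; for the fixture used in tests the pair
signal is given bandwidth up to 2 Hz and independent noise high-passed
at 2 Hz so the crossing falls in the 1–3 Hz band that motivates the
1 Hz analysis cutoff.

## Encoding models

`EncodingModel` fits ridge regressions of dF/F on the six behavioral
predictors after 1 Hz low-passing everything.  Cross-validation uses
contiguous time blocks (never shuffled samples — autocorrelation would
leak across folds), with the penalty chosen on inner blocked folds from
10 log-spaced values over 1e−3…1e3 on train-standardized predictors.
Out-of-sample R² is pooled over held-out blocks and may be negative.
Per-predictor variance is reported two ways, side by side:
cross-validated single-predictor R², and the unique contribution
ΔR² = full − full-without-that-predictor.  An optional
`predictor_kernel` convolves predictors with an indicator kernel before
fitting, putting them on the same temporal footing as the
indicator-filtered response — standard practice in calcium encoding
models; it is off by default.

**Session permutation.** The prediction-error metric is blocked-CV mean
squared error normalized by response variance (so sessions of different
amplitude are comparable).  The matched statistic is the mean error over
the diagonal (response *i* predicted from predictors *i*); the null is
the set of mean errors over all derangements (complete unmatched
assignments), enumerated exactly for up to 8 sessions and sampled
beyond.  Using derangement *means* makes the matched statistic
exchangeable with the null when responses and predictors are unrelated,
so its percentile is uniform under the null and the ≤ 5th-percentile
"valid" flag has its nominal level.

## Correlation structure

The decomposition low-passes at 1 Hz, z-scores each trace, and computes
for every pair the ordinary Pearson correlation and the partial
correlation given the leave-two-out common signal, via the closed form
on the sample correlations (algebraically identical to regressing both
traces on the common signal and correlating residuals; the equality is
enforced to 1e−10 in tests).  Vectorization uses the population Gram
matrix, so a session with dozens of objects decomposes in milliseconds.

**Finite-population bias.** With n simultaneously recorded objects the
common signal is an average of n−2 traces and carries 1/(n−2) of their
average noise; for a population coupled purely through a common drive
the expected partial correlation is ≈ +1/(n−1), not exactly zero.  This
is a property of the leave-two-out estimator itself (the paper-scale
populations of 7–61 simultaneous axons keep it small).  Ground-truth
checks that assert |mean partial r| < 0.05 therefore use populations of
30 axons.  The session-mean variant (pair included in its own control)
is available behind `leave_two_out=False` for sensitivity analysis; on
small populations it contaminates the control with the pair's own noise
and pulls partial correlations down, which is why leave-two-out is the
default everywhere.

Distance is Euclidean between ROI centers in mm; pairs within one ROI
are 0 mm apart.  Distance trends are Pearson correlations of
(distance, r) over non-same-axon pairs with permutation p-values
obtained by shuffling the object-to-position assignment and recomputing
pair distances.  State-restricted analyses build sample masks from the
behavioral traces interpolated onto the dF/F grid (stationary: speed
≤ 2.5 cm/s; still: additionally normalized whisker MEI ≤ 0.2), filter
first and mask second (filtering concatenated fragments would create
edge artifacts), require ≥ 60 s of retained data per mode, and compare
ordinary-minus-partial differences across modes with a paired t-test.
The movement-decorrelation control computes same-axon pair correlations
separately within walking and non-walking samples; a drop during
walking flags that apparent state-dependent decorrelation of
heterogeneous pairs is a measurement artifact of the frequency-limited
indicator, not biology.

## Problem sizes and determinism

Simulated checks use 4–30 minute sessions at 10–30 Hz imaging with
3–30 objects, 50 seeds for distributional claims, 1000 shuffles for null
calibration, and 20 replicates for permutation validity — sizes chosen
so the full suite and the acceptance script each finish in about a
minute while leaving the asserted quantities' Monte-Carlo error well
inside the asserted tolerances.  All randomness flows from explicit
`numpy` Generators seeded from the session/config seed; result tables
are written with a fixed float format and no timestamps, so rerunning
any pipeline with the same seed and configuration reproduces outputs
byte for byte.

## Known limitations

- The semi-Markov behavior model is a caricature; duration distributions
  and rates are placeholders exposed in `SimConfig`.
- The sustainedness index and cross-correlation peak lag inherit
  indicator-kinetics bias under the default slow kernel (quantified
  above); the package measures the statistics as defined rather than
  deconvolving them.
- The SNR criterion's spectral estimator (Welch, 60 s windows) is a
  package choice; other estimators shift the statistic slightly relative
  to the log 20 threshold.
- Partial correlations assume linear, stationary coupling to a single
  common signal; multiple latent drives would require the precision
  matrix or factor models, which are out of scope.
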