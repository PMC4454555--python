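# Methods

This note documents the model, the numerical choices, and the design
decisions behind `emgonset`, in enough detail that a careful user can
judge what the tests do and do not establish.

## Signal model and features

Surface EMG during a contraction is treated as band-limited Gaussian noise:
white Gaussian noise shaped by

    H(s) = k · s · (2π f_h)² / ((s + 2π f_l)(s + 2π f_h)²),

a band-pass with a zero at DC and poles at f_l = 80 Hz and (doubly) at
f_h = 120 Hz, whose magnitude peaks near 73 Hz and rolls off at −40 dB/dec.
This is the classic interference-pattern spectrum of surface EMG.  The
filter is discretised by the bilinear transform at the trial's sampling
rate (2 kHz by default), and k is normalised so the analog peak gain is 1 —
burst amplitude is then controlled solely by the burst gains.

Features are per-frame subband log energies: Hanning frames of 32 ms with a
14 ms hop ("overlap step" read as the frame shift), a 64-point FFT at
2 kHz (31.25 Hz per bin), and eight Mel-spaced bin groups — (1–3), (4–6),
(7–9), (10–13), (14–17), (18–22), (23–27), (28–33) in 1-based indexing with
bin 1 = DC.  The groups are authoritative at 2 kHz; at other rates they are
recomputed by mapping Mel-spaced edges over 0..min(1000, fs/2) Hz to bins,
a construction that reproduces the canonical groups exactly at 2 kHz.  The
band value is the mean bin power in dB; bin powers are floored at 10⁻¹² of
the frame's maximum bin power so silent frames stay finite.  Each band's
sequence is smoothed by a 5-point centred running median (shrinking,
symmetric windows at the edges).

## The sequential mixture

Each band's envelope is a two-component Gaussian mixture: component 0 =
non-burst (noise) log powers, component 1 = burst log powers.  Parameters
per band: weights (w₀, w₁) — the prior burst absence/presence
probabilities — means μ₀, μ₁ (dB) and variances κ₀, κ₁ (dB²).

**Initialisation.**  Batch EM on the first M = 80 frames (≈1.1 s), started
deterministically from the 25th/75th percentiles with shared sample
variance and equal weights, iterated until the log-likelihood gain drops
below 10⁻⁶ (at most 300 iterations).  An MDL test, −logL(n) + (p_n/2) ln M
with p₁ = 2 and p₂ = 5 free parameters, decides whether a burst component
is present at all.  Two robustness measures proved necessary:

* *Variance floor.*  The running median produces exact value repeats, and
  unfloored EM collapses a component onto such a tie with unbounded
  likelihood, which fools the MDL test.  Component variances are floored at
  (0.25 σ_MAD)², far below any genuine burst/non-burst separation.
* *Lower-minority gate.*  Log-power noise is left-skewed; EM sometimes
  splits off a small low tail as a spurious "non-burst" cluster, which
  inverts the labels (the noise bulk becomes the burst component) and
  permanently corrupts the band.  A two-component fit whose *lower*
  component holds under 20 % of the frames is therefore treated as
  noise-only.  A small *upper* minority is legitimate — that is a burst
  entering late in the initialisation window — and is kept.
* *Minimum-separation gate.*  The same skewness also produces
  near-symmetric splits whose component gap is comparable to δ; thresholds
  derived from them sit inside the noise distribution and cause
  seconds-long false-activity transients after initialisation.  Measured
  on this simulator, spurious noise splits separate by at most ≈5 dB while
  genuine burst/non-burst splits separate by ≥ ≈7 dB, so fits with
  μ₁ − μ₀ < 1.5 δ fall back to the noise-only (virtual-component)
  initialisation, which explains such windows equally well.

When initialisation is noise-only, the burst component is constructed as a
*virtual* component: μ₁ = μ₀ + δ, κ₁ = κ₀, w₁ = ε.  The first M frames are
classified retroactively with the initial model so the decision sequence
covers the whole trial; this is what removes the quiet-start assumption.

**Sequential updates.**  With forgetting factor α = 0.99 (effective window
L = 1/(1−α) = 100 frames ≈ 1.4 s), posteriors are computed under the old
model and weights/means/variances are updated by the first-order
recursions, the mean and variance recursions dividing by the
already-updated weight.  After every update the constraints are applied, in
this order: μ₁ ← max(μ₁, μ₀ + δ); κ₁ ← max(κ₀, κ₁); w₁ ← max(w₁, ε) with
w₀ = 1 − w₁.  Applying constraints last keeps the threshold always
well-defined.  δ = 3.5 dB trades false alarms (larger δ) against missed
weak bursts (smaller δ); ε = 0.03 keeps the burst prior from vanishing so
the model can re-enter the burst state.  Non-finite observations are
skipped with a warning.

**Decision threshold.**  The minimum-classification-error boundary solves
w₁ f₁(θ) = w₀ f₀(θ).  With equal variances the closed form
θ = (μ₀+μ₁)/2 + κ ln(w₀/w₁)/(μ₁−μ₀) applies; otherwise equating the
weighted log-densities gives a quadratic whose root nearest the inter-mean
interval is the decision boundary (the far-tail crossing is a local
*maximum* of the error and is discarded; ties break toward the larger
root).  When the densities never cross — possible for degenerate states
where the wide burst component dominates everywhere — the Bayes-rule limit
is returned (±∞: classify everything as the dominant class) instead of
failing.

## Voting and segments

A frame's vote count is the number of bands whose envelope strictly
exceeds their threshold.  Frames with ≥ 3 of 8 votes are active.  The vote
threshold deserves comment: the shaped burst (80–120 Hz) carries detectable
energy in only the three or four lowest Mel bands — the top bands lie in
the 20–500 Hz conditioning filter's stopband — so demanding a majority of
all eight bands suppresses exactly the low-SNR detections the framework
exists for.  Measurements during development showed majority voting makes
2 dB detection all-or-nothing and misses low-SNR bursts in time-varying
trials, while 3-of-8 voting detects them; the false-alarm cost of the
lower threshold is absorbed by run post-processing: gaps shorter than
150 ms are merged (a sub-150 ms dropout is not a separate contraction) and
runs shorter than 200 ms are dropped (voluntary bursts persist for hundreds
of ms; all simulated bursts are ≥ 400 ms).  With these defaults 60-s
pure-noise trials almost never produce a false segment.

Onset/offset timestamps use the *centre* of the first/last active frame's
analysis window.  A voting frame only shows that activity started
somewhere inside its 32 ms window; the centre is the minimum-worst-case
convention, whereas the window start systematically claims activity up to
32 ms early — which, under the absolute-latency metric, made latency
*improve* as SNR dropped.

## Simulator

`simulate_clean_emg` prepends and discards 0.5 s of shaped noise so burst
interiors are stationary, and gates with a rectangular envelope (an
optional raised-cosine ramp is available).  SNR is defined as mean clean
burst power *within the burst intervals* over the added noise variance —
the whole-trial alternative would inflate the nominal SNR by the duty
cycle.  `add_noise_for_snr` supports piecewise noise schedules (per-segment
noise scaling); `varying_snr_trial` defaults instead to a constant noise
floor with per-segment burst rescaling (`mode="burst_gain"`).  The
distinction matters: a step increase in the noise floor is statistically
indistinguishable from a burst — the posterior assigns the step to the
burst component, μ₀ freezes (its update weight vanishes), and everything
after the step stays active.  Contraction-strength variation over a
stationary background is both the physically common case and the regime an
adaptive detector can actually track, so it is the default; the
noise-scaling mode is retained for completeness.

The 20–500 Hz 6th-order Butterworth conditioning ("order" = overall
band-pass order) is zero-phase by default for offline use; the evaluation
harness conditions causally (`zero_phase=False`), because zero-phase
filtering smears burst energy backwards in time and biases onset-latency
measurements early.

## Reference detectors

All three baselines estimate noise statistics from a window assumed
activity-free (the first 0.5 s by default) — the supervised ingredient the
sequential GMM removes — and search for the onset after that window.

* **AMP** rectifies the signal and smooths with a *causal* 50 ms moving
  average; the onset is the first time the envelope stays above threshold
  for 25 ms (`min_hold_ms`; isolated noise spikes otherwise trigger early
  false crossings).  The default threshold is 3 × SD of the *raw* baseline
  signal — the classical "k standard deviations of the background noise"
  rule.  An alternative (`amp_stats="envelope"`) thresholds at
  mean + 3 SD of the smoothed envelope itself; because smoothing shrinks
  the baseline SD this variant is far more sensitive (it still detects
  2 dB bursts within ~20 ms) and, notably, does *not* reproduce the steep
  low-SNR degradation of amplitude detectors that motivates unsupervised
  methods.  The raw form is the default for that reason.
* **TKEO** applies ψ[n] = x[n]² − x[n−1]x[n+1] to the raw signal, rectifies
  and smooths identically, and thresholds at mean + 6 SD of the smoothed
  TKE baseline (a pure 6 SD variant via `threshold_form="k_sd"`).
* **Double threshold** squares successive baseline-normalised sample pairs
  (z ~ χ² with 2 degrees of freedom under noise), compares against
  ζ = the χ²₂ 99th percentile (a deterministic 1 % per-sample false-alarm
  design), requires r₀ = 2 exceedances within m = 5 successive z-samples
  (r₀ = 1 lets isolated noise pairs spawn false runs), and accepts runs
  persisting ≥ 30 ms.  Whitening is approximated by baseline-SD
  normalisation.

## Evaluation harness

Latency is τ = |t_d − t₀|; early detections are penalised like late ones.
A detection is matched to a true onset only within ±0.5 s — for every
method, baselines included — otherwise the trial counts as missed; a
crossing a second before the burst is a false alarm, not a latency.
Reports keep the survivor mean ± SE plus the missed count.  For *ordering*
comparisons across SNR levels the acceptance checks use means censored at
the 0.5 s bound, because survivor-only means are flattered exactly where a
detector degrades (a level where most trials are missed can show a small
mean over the few easy survivors).

The comparison protocol is 4-s trials with one burst from 1 to 3 s (true
onset 1 s).  The default sweep runs 20 trials per SNR level over
{20, 10, 8, 5, 2} dB to keep the test suite fast; the CLI exposes
`--n-trials 60` and the full level list {20, 15, 10, 8, 5, 4, 3, 2} dB for
the complete protocol.  The same clean trials are reused across SNR
levels, and within a (trial, SNR) cell all methods see the same noise
realisation, so method comparisons are paired.

The multi-burst protocol is a 12-s trial with five bursts of different
durations (0.4–1.2 s) and amplitudes (gains 0.9–1.25), onsets at 1.0, 3.0,
5.0, 7.5, 9.0 s; the time-varying protocol assigns 20/10/2 dB to the three
4-s thirds of that trial.

## What the synthetic data does and does not show

The simulator produces stationary, band-limited Gaussian bursts with sharp
rectangular envelopes in white Gaussian noise.  Real surface EMG has
gradual recruitment ramps, motor-unit structure, powerline and motion
artefacts, and nonstationary baselines; none of these are modelled, and
the non-goals are explicit: no physiological motor-unit models, no
multi-channel simulation, no coloured noise.  Passing tests therefore
establish internal correctness (formulas, constraints, thresholds,
bookkeeping) and *relative* detector behaviour under the stated noise
model — not clinical performance.  Latency floors are also convention-bound
(frame quantisation at a 14 ms hop, envelope ramp times), so absolute
millisecond values should be compared only within this framework.

## Known limitations

* A sustained step increase of the noise floor is detected as activity
  (see above); tracking such steps would need an explicit noise-floor
  re-estimation mechanism outside the first-order recursions.
* The burst-component mean has no downward dynamics during long quiet
  stretches when its variance is small: after a strong contraction, μ₁ can
  linger high until occasional upper-tail noise frames (weighted by the
  floored prior ε) pull it down, which slows re-sensitisation to much
  weaker bursts.  In practice bursts near 2 dB SNR that follow much
  stronger activity are detected only intermittently.
* Votes are integer counts over eight fixed bands; signals whose energy is
  concentrated outside 20–500 Hz, or sampling rates far from 2 kHz, need a
  custom band layout (`FrameConfig.band_bins`).
* Single-channel only.
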