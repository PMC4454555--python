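# emgonset

Unsupervised muscle-activity onset/offset detection from single-channel
surface electromyography (EMG).

Detecting when a muscle switches on is a prerequisite for gait analysis,
myoelectric prosthesis control and many other EMG applications.  Classical
detectors threshold an amplitude envelope against statistics of a
known-quiet baseline window — a supervised assumption that breaks down when
the signal-to-noise ratio (SNR) is low or changes over time.  `emgonset`
implements an unsupervised alternative for researchers working with noisy
or nonstationary recordings: a **constrained sequential two-component
Gaussian mixture model (GMM)** over subband log power.

## The model

The signal is chopped into Hanning-windowed frames (32 ms window, 14 ms
hop), transformed by FFT, and grouped into N = 8 Mel-spaced subbands.  The
subband log energy of frame ℓ in band n is

    x̄_ℓ = 10 log10( (1/(f_{n+1}−f_n)) Σ_{j=f_n}^{f_{n+1}−1} |Y_{ℓ,j}|² )   [dB]

smoothed by a 5-point running median into the envelope x_ℓ.  Each band's
envelope is modelled as a mixture of a non-burst (noise) and a burst
component,

    p(x | λ) = w₀ N(x; μ₀, κ₀) + w₁ N(x; μ₁, κ₁),

initialised by batch EM on the first M = 80 frames (a minimum-description-
length test decides whether a burst component is present at all) and then
updated frame by frame with first-order recursions under a forgetting
factor α = 0.99:

    w_i  ← α w_i + (1−α) p_i
    μ_i  ← (α w_i μ_i + (1−α) p_i x) / w_i
    κ_i  ← (α w_i κ_i + (1−α) p_i (x − μ_i)²) / w_i

where p_i is the posterior of component i under the previous model.  Three
constraints keep the model discriminative through long burst-free
stretches:  μ₁ ≥ μ₀ + δ (δ = 3.5 dB), κ₁ ≥ κ₀, and w₁ ≥ ε (ε = 0.03).
Each band classifies each frame with the minimum-classification-error
threshold where the weighted component densities cross, and frames where at
least 3 of the 8 bands exceed their thresholds are declared active; merged
runs become onset/offset segments.  No quiet baseline is assumed — a burst
that starts at t = 0 is still found.

The package also ships:

* a surface-EMG simulator (white Gaussian noise shaped by the band-pass
  filter H(s) = k·s·(2πf_h)² / ((s+2πf_l)(s+2πf_h)²) with f_l = 80 Hz,
  f_h = 120 Hz, gated by ground-truth bursts, with SNR-controlled additive
  noise and 20–500 Hz Butterworth conditioning),
* three classical reference detectors (amplitude thresholding,
  Teager-Kaiser energy thresholding, and a Bonato-style double threshold),
* a latency evaluation harness (τ = |t_d − t₀|) sweeping SNR levels with
  noise realisations paired across methods.

## Worked example

```python
import numpy as np
from emgonset import (BurstSpec, SequentialGmmDetector, add_noise_for_snr,
                      condition_signal, simulate_clean_emg)

bursts = [BurstSpec(1.0, 2.2, gain=1.0), BurstSpec(3.5, 4.6, gain=0.8)]
clean = simulate_clean_emg(6.0, fs=2000.0, bursts=bursts, seed=42)
noisy = add_noise_for_snr(clean, snr_db=8.0, seed=43)
trial = condition_signal(noisy)

detector = SequentialGmmDetector(fs=2000.0).fit(trial.samples)
for onset, offset in detector.segments_:
    print(f"activity from {onset:6.3f} s to {offset:6.3f} s")
print("mean votes inside segments:", round(detector.votes_[detector.labels_ == 1].mean(), 2))
```

prints

```
activity from  0.996 s to  2.214 s
activity from  3.502 s to  4.594 s
mean votes inside segments: 3.85
```

Both simulated contractions (true onsets 1.0 s and 3.5 s) are recovered
within ~5 ms at 8 dB SNR, and inside the detected segments an average of
3.85 of the 8 frequency bands vote for burst presence.  `detector.prob_map_`
holds the per-band burst presence probabilities (a time-frequency soft
detection map), `detector.thresholds_` the adaptive per-band thresholds in
dB.

The same pipeline is available from the shell:

```
emgonset simulate --duration 6 --bursts bursts.csv --snr 8 --seed 42 --out sig.txt --truth truth.tsv
emgonset detect --input sig.txt --fs 2000 --out-dir results/
emgonset evaluate --methods sgmm,amp,tkeo,bonato --snrs 20,10,8,5,2 --n-trials 20 --seed 0 --out-dir sweep/
```

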