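"""Reference onset detectors used for performance comparison.

Three classical single-threshold/double-threshold schemes:

* AMP — amplitude thresholding: the rectified signal is smoothed with a
  moving average and the onset is the first crossing of
  ``baseline mean + 3 SD`` of the smoothed rectified baseline.
* TKEO — the discrete Teager-Kaiser energy operator
  ``psi[n] = x[n]^2 - x[n-1] x[n+1]`` is applied to the raw signal, the
  rectified TKE series is smoothed the same way, and the threshold is
  ``baseline mean + 6 SD`` of the smoothed TKE baseline (a pure ``6 SD``
  variant is available via ``threshold_form="k_sd"``).
* Bonato-style double threshold: squared sums of successive
  baseline-normalised sample pairs ``z[k] = y[2k]^2 + y[2k+1]^2`` are
  compared against a first threshold zeta (by default the 99th percentile of
  the baseline z values); z-samples covered by an m-sample observation
  window containing at least r0 exceedances are active, and active runs
  shorter than a minimum duration are discarded.

All three assume an activity-free baseline window at the start of the trial
for noise statistics — the supervised ingredient the sequential-GMM
framework removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .simulate import EmgTrial

__all__ = [
    "BaselineConfig",
    "tke_operator",
    "amp_detect",
    "tkeo_detect",
    "bonato_detect",
    "AmplitudeOnsetDetector",
    "TkeoOnsetDetector",
    "DoubleThresholdOnsetDetector",
]


@dataclass
class BaselineConfig:
    """Shared configuration for the reference detectors.

    baseline_window_s : interval assumed activity-free for noise statistics.
    amp_k / tkeo_k : SD multipliers of the respective thresholds.
    amp_stats : "raw" (default) thresholds the envelope at
        ``amp_k * SD(raw baseline signal)``; "envelope" uses
        ``mean + amp_k * SD`` of the smoothed rectified baseline envelope
        instead.  The raw form is the classical "k standard deviations of
        the background noise" rule; the envelope form is far more sensitive
        because smoothing shrinks the baseline SD.
    threshold_form : "mean_plus_k_sd" (default) or "k_sd"; applies to the
        envelope-statistics thresholds (TKEO, and AMP with
        ``amp_stats="envelope"``).
    min_hold_ms : the envelope must stay above threshold for this long
        before a crossing counts as an onset (rejects isolated noise
        spikes); the onset is reported at the start of the hold, so no
        latency bias is introduced.
    bonato_zeta : first threshold on z; None uses the 99th percentile of the
        chi-square(2) distribution the whitened noise pairs follow (a 1%
        per-sample false-alarm design).
    bonato_m / bonato_r0 : observation window length in z-samples and the
        required number of exceedances within it.
    bonato_min_active_ms : shortest accepted activity duration.
    """

    baseline_window_s: tuple[float, float] = (0.0, 0.5)
    amp_k: float = 3.0
    tkeo_k: float = 6.0
    smoothing_ms: float = 50.0
    min_hold_ms: float = 25.0
    amp_stats: str = "raw"
    threshold_form: str = "mean_plus_k_sd"
    bonato_zeta: float | None = None
    bonato_m: int = 5
    bonato_r0: int = 2
    bonato_min_active_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.amp_k <= 0 or self.tkeo_k <= 0:
            raise ValueError("amp_k and tkeo_k must be positive")
        if not 1 <= self.bonato_r0 <= self.bonato_m:
            raise ValueError(
                f"need 1 <= r0 <= m, got r0={self.bonato_r0}, m={self.bonato_m}"
            )
        if self.threshold_form not in ("mean_plus_k_sd", "k_sd"):
            raise ValueError(f"unknown threshold_form {self.threshold_form!r}")
        if self.amp_stats not in ("raw", "envelope"):
            raise ValueError(f"unknown amp_stats {self.amp_stats!r}")


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Causal (trailing) moving average; the first samples use a growing
    window.  A centred window would smear burst energy backwards in time and
    make high-SNR onsets appear before the true onset."""
    n = max(int(n), 1)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(len(x))
    out[:n] = csum[1 : n + 1] / np.arange(1, n + 1)
    out[n:] = (csum[n + 1 :] - csum[1:-n]) / n
    return out


def _baseline_slice(config: BaselineConfig, fs: float, n: int) -> slice:
    b0, b1 = config.baseline_window_s
    i0, i1 = int(round(b0 * fs)), int(round(b1 * fs))
    if not 0 <= i0 < i1 <= n:
        raise ValueError(f"baseline window {config.baseline_window_s} outside trial")
    return slice(i0, i1)


def _threshold(baseline: np.ndarray, k: float, form: str) -> float:
    mean = float(np.mean(baseline))
    sd = float(np.std(baseline))
    return k * sd if form == "k_sd" else mean + k * sd


def _first_crossing(
    env: np.ndarray,
    threshold: float,
    fs: float,
    min_hold_ms: float = 0.0,
    search_from: int = 0,
) -> float | None:
    """First time env stays above threshold for min_hold_ms, at/after search_from."""
    above = env > threshold
    above[:search_from] = False
    hold = max(int(round(min_hold_ms / 1000.0 * fs)), 1)
    if hold == 1:
        idx = np.flatnonzero(above)
        return float(idx[0] / fs) if len(idx) else None
    counts = np.convolve(above.astype(int), np.ones(hold, dtype=int), mode="valid")
    starts = np.flatnonzero(counts == hold)
    return float(starts[0] / fs) if len(starts) else None


def amp_detect(trial: EmgTrial, config: BaselineConfig | None = None) -> float | None:
    """Amplitude-threshold onset; None when the threshold is never exceeded."""
    if config is None:
        config = BaselineConfig()
    env = _moving_average(np.abs(trial.samples), config.smoothing_ms / 1000.0 * trial.fs)
    bsl = _baseline_slice(config, trial.fs, len(env))
    if config.amp_stats == "raw":
        thr = config.amp_k * float(np.std(trial.samples[bsl]))
    else:
        thr = _threshold(env[bsl], config.amp_k, config.threshold_form)
    return _first_crossing(env, thr, trial.fs, config.min_hold_ms, bsl.stop)


def tke_operator(x: np.ndarray) -> np.ndarray:
    """Discrete Teager-Kaiser energy, endpoints copied from their neighbours."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples, got {len(x)}")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def tkeo_detect(trial: EmgTrial, config: BaselineConfig | None = None) -> float | None:
    """TKE-threshold onset; None when the threshold is never exceeded."""
    if config is None:
        config = BaselineConfig()
    psi = tke_operator(trial.samples)
    env = _moving_average(np.abs(psi), config.smoothing_ms / 1000.0 * trial.fs)
    base = env[_baseline_slice(config, trial.fs, len(env))]
    thr = _threshold(base, config.tkeo_k, config.threshold_form)
    start = _baseline_slice(config, trial.fs, len(env)).stop
    return _first_crossing(env, thr, trial.fs, config.min_hold_ms, start)


def _bonato_active(z: np.ndarray, zeta: float, m: int, r0: int) -> np.ndarray:
    """z-samples covered by any m-window containing >= r0 exceedances."""
    above = (z > zeta).astype(int)
    if len(above) < m:
        return np.zeros(len(above), dtype=bool)
    counts = np.convolve(above, np.ones(m, dtype=int), mode="valid")
    ok = counts >= r0  # window starting at k covers z[k : k + m]
    active = np.zeros(len(z), dtype=bool)
    for k in np.flatnonzero(ok):
        active[k : k + m] = True
    return active


def bonato_detect(trial: EmgTrial, config: BaselineConfig | None = None) -> float | None:
    """Double-threshold onset on baseline-normalised sample pairs.

    Whitening is approximated by dividing by the baseline standard
    deviation.  Returns the time of the first raw sample contributing to the
    first accepted active run, or None.
    """
    if config is None:
        config = BaselineConfig()
    x = trial.samples
    base = x[_baseline_slice(config, trial.fs, len(x))]
    sd = float(np.std(base))
    if sd == 0:
        return None
    y = x / sd
    n_pairs = len(y) // 2
    z = y[: 2 * n_pairs : 2] ** 2 + y[1 : 2 * n_pairs : 2] ** 2
    if config.bonato_zeta is not None:
        zeta = config.bonato_zeta
    else:
        # whitened noise pairs give z ~ chi-square(2); 1% false-alarm design
        zeta = float(chi2.ppf(0.99, df=2))
    active = _bonato_active(z, zeta, config.bonato_m, config.bonato_r0)
    min_run = max(int(round(config.bonato_min_active_ms / 1000.0 * trial.fs / 2)), 1)
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    base_end = _baseline_slice(config, trial.fs, len(x)).stop // 2
    for s, e in zip(starts, ends):
        if e < base_end:
            continue
        if e - s + 1 >= min_run:
            # first z in the run that actually exceeds zeta
            run = np.arange(s, e + 1)
            exceed = run[z[run] > zeta]
            k = int(exceed[0]) if len(exceed) else int(s)
            return float(2 * k / trial.fs)
    return None


class _BaselineOnsetEstimator(BaseEstimator):
    """Common sklearn-style surface for the single-onset baseline detectors."""

    _detect = None  # set in subclasses

    def __init__(
        self,
        fs: float = 2000.0,
        baseline_window_s: tuple[float, float] = (0.0, 0.5),
        smoothing_ms: float = 50.0,
    ):
        self.fs = fs
        self.baseline_window_s = baseline_window_s
        self.smoothing_ms = smoothing_ms

    def _config(self) -> BaselineConfig:
        return BaselineConfig(
            baseline_window_s=self.baseline_window_s, smoothing_ms=self.smoothing_ms
        )

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        onset = type(self)._detect(EmgTrial(samples=x, fs=self.fs), self._config())
        self.detected_ = onset is not None
        self.onset_s_ = float(onset) if onset is not None else float("nan")
        return self


class AmplitudeOnsetDetector(_BaselineOnsetEstimator):
    """Rectified-amplitude moving-average threshold detector."""

    _detect = staticmethod(amp_detect)


class TkeoOnsetDetector(_BaselineOnsetEstimator):
    """Teager-Kaiser energy threshold detector."""

    _detect = staticmethod(tkeo_detect)


class DoubleThresholdOnsetDetector(_BaselineOnsetEstimator):
    """Bonato-style double-threshold detector."""

    _detect = staticmethod(bonato_detect)
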