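"""Synthetic surface-EMG generation.

Clean EMG interference patterns are emulated by shaping white Gaussian noise
with a band-pass filter whose transfer function

    H(s) = k * s * (2*pi*fh)**2 / ((s + 2*pi*fl) * (s + 2*pi*fh)**2)

concentrates power between the two cut-offs (defaults 80 and 120 Hz, the
classic spectral shape of a surface-EMG interference pattern).  Muscle
activity is imposed by gating the shaped noise with rectangular (optionally
raised-cosine ramped) burst envelopes, and recording noise is added as
independent white Gaussian noise scaled to a requested signal-to-noise ratio.
The SNR is defined over the burst intervals:

    SNR_dB = 10 * log10( mean burst-signal power within bursts / noise variance )

All generators are deterministic for a fixed seed, so every trial carries
exact ground-truth onset/offset annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ShapingFilterSpec",
    "BurstSpec",
    "EmgTrial",
    "default_shaping_filter",
    "shaping_filter_gain",
    "simulate_clean_emg",
    "add_noise_for_snr",
    "condition_signal",
    "FIVE_BURST_SPECS",
]


@dataclass(frozen=True)
class ShapingFilterSpec:
    """Continuous-time shaping filter for clean surface EMG.

    Parameters
    ----------
    k : float
        Dimensionless scaling factor (peak-gain normalisation lives here).
    fl, fh : float
        Low/high cut-off frequencies in Hz; ``0 < fl < fh``.
    """

    k: float = 1.0
    fl: float = 80.0
    fh: float = 120.0

    def __post_init__(self) -> None:
        if not self.fl > 0:
            raise ValueError(f"fl must be positive, got {self.fl}")
        if not self.fh > self.fl:
            raise ValueError(f"fh must exceed fl, got fl={self.fl}, fh={self.fh}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")

    def analog_tf(self) -> tuple[np.ndarray, np.ndarray]:
        """Numerator/denominator of H(s) in descending powers of s."""
        wl = 2.0 * math.pi * self.fl
        wh = 2.0 * math.pi * self.fh
        num = np.array([self.k * wh**2, 0.0])
        den = np.poly([-wl, -wh, -wh]).real
        return num, den


def shaping_filter_gain(spec: ShapingFilterSpec, f):
    """Frequency response H(j*2*pi*f) of the shaping filter.

    Parameters
    ----------
    spec : ShapingFilterSpec
    f : float or array_like
        Frequency in Hz, non-negative.

    Returns
    -------
    complex or ndarray of complex
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("frequency must be non-negative")
    s = 1j * 2.0 * math.pi * f_arr
    wl = 2.0 * math.pi * spec.fl
    wh = 2.0 * math.pi * spec.fh
    h = spec.k * s * wh**2 / ((s + wl) * (s + wh) ** 2)
    return complex(h) if np.isscalar(f) or f_arr.ndim == 0 else h


def _peak_gain(spec: ShapingFilterSpec, f_max: float = 1000.0, df: float = 0.1) -> float:
    grid = np.arange(0.0, f_max + df, df)
    return float(np.max(np.abs(shaping_filter_gain(spec, grid))))


def default_shaping_filter(fl: float = 80.0, fh: float = 120.0) -> ShapingFilterSpec:
    """Shaping filter with k normalised so the analog peak gain is 1.

    Burst amplitude is then controlled solely by :class:`BurstSpec.gain`.
    """
    base = ShapingFilterSpec(k=1.0, fl=fl, fh=fh)
    return replace(base, k=1.0 / _peak_gain(base))


@dataclass(frozen=True)
class BurstSpec:
    """One ground-truth muscle activity burst."""

    onset_s: float
    offset_s: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError(
                f"need 0 <= onset < offset, got {self.onset_s}, {self.offset_s}"
            )
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


# Five bursts of different durations and amplitudes over a 12 s trial, the
# multi-burst layout used by the detection examples and the time-varying-SNR
# protocol (gaps are wide enough that detected segments never merge).
FIVE_BURST_SPECS: tuple[BurstSpec, ...] = (
    BurstSpec(1.0, 1.8, 1.0),
    BurstSpec(3.0, 3.6, 1.25),
    BurstSpec(5.0, 6.2, 0.9),
    BurstSpec(7.5, 7.9, 1.1),
    BurstSpec(9.0, 10.0, 1.0),
)


def _validate_bursts(bursts: Sequence[BurstSpec], duration_s: float) -> tuple[BurstSpec, ...]:
    bursts = tuple(bursts)
    for b in bursts:
        if b.offset_s > duration_s:
            raise ValueError(f"burst {b} extends past trial end {duration_s} s")
    for prev, cur in zip(bursts, bursts[1:]):
        if cur.onset_s < prev.offset_s:
            raise ValueError(f"bursts overlap or are unsorted: {prev} then {cur}")
    return bursts


@dataclass
class EmgTrial:
    """A sampled EMG signal with optional ground-truth annotations.

    Attributes
    ----------
    samples : ndarray
        Amplitude series (arbitrary units).
    fs : float
        Sampling rate in Hz.
    bursts : tuple of BurstSpec
        Ground-truth activity intervals (may be empty).
    snr_db : float or list of ((t0, t1), snr_db) or None
        SNR label(s) attached when noise was added.
    """

    samples: np.ndarray
    fs: float
    bursts: tuple[BurstSpec, ...] = ()
    snr_db: object = None

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        self.bursts = tuple(self.bursts)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def burst_mask(self) -> np.ndarray:
        """Boolean mask of samples inside any ground-truth burst."""
        mask = np.zeros(len(self.samples), dtype=bool)
        for b in self.bursts:
            i0 = int(round(b.onset_s * self.fs))
            i1 = int(round(b.offset_s * self.fs))
            mask[i0:i1] = True
        return mask

    def with_samples(self, samples: np.ndarray) -> "EmgTrial":
        return EmgTrial(samples=samples, fs=self.fs, bursts=self.bursts, snr_db=self.snr_db)


def _gate(n: int, fs: float, bursts: Sequence[BurstSpec], ramp_ms: float) -> np.ndarray:
    gate = np.zeros(n)
    for b in bursts:
        i0 = int(round(b.onset_s * fs))
        i1 = int(round(b.offset_s * fs))
        gate[i0:i1] = b.gain
        nr = int(round(ramp_ms / 1000.0 * fs))
        if nr > 0 and 2 * nr < i1 - i0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
            gate[i0 : i0 + nr] = b.gain * ramp
            gate[i1 - nr : i1] = b.gain * ramp[::-1]
    return gate


def simulate_clean_emg(
    duration_s: float,
    fs: float = 2000.0,
    bursts: Sequence[BurstSpec] = (),
    spec: ShapingFilterSpec | None = None,
    seed: int | np.random.Generator = 0,
    warmup_s: float = 0.5,
    ramp_ms: float = 0.0,
) -> EmgTrial:
    """Simulate noise-free gated surface EMG.

    White Gaussian noise is passed through the shaping filter (discretised by
    the bilinear transform at ``fs``) and multiplied by the burst gating
    envelope: ``gain`` inside bursts, exactly zero outside.  ``warmup_s`` of
    shaped noise is prepended and discarded so the burst interiors are
    stationary (the filter's transient never reaches them).
    """
    bursts = _validate_bursts(sorted(bursts, key=lambda b: b.onset_s), duration_s)
    if spec is None:
        spec = default_shaping_filter()
    n = int(round(duration_s * fs))
    n_warm = int(round(warmup_s * fs))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n + n_warm)
    num, den = spec.analog_tf()
    b, a = sps.bilinear(num, den, fs=fs)
    shaped = sps.lfilter(b, a, white)[n_warm:]
    samples = shaped * _gate(n, fs, bursts, ramp_ms)
    return EmgTrial(samples=samples, fs=fs, bursts=bursts)


def _noise_sigma(clean: np.ndarray, mask: np.ndarray, snr_db: float) -> float:
    p_burst = float(np.mean(clean[mask] ** 2))
    return math.sqrt(p_burst / 10.0 ** (snr_db / 10.0))


def add_noise_for_snr(
    trial: EmgTrial,
    snr_db,
    seed: int | np.random.Generator = 0,
) -> EmgTrial:
    """Add white Gaussian noise scaled to a requested SNR.

    ``snr_db`` may be a scalar (one noise level over the whole trial) or a
    piecewise schedule ``[((t0_s, t1_s), snr_db), ...]`` with non-overlapping
    intervals, each scaled from the burst power inside that interval (the
    global burst power is used for intervals containing no burst samples).
    An infinite SNR returns the trial unchanged.
    """
    clean = trial.samples
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(snr_db):
        if np.isinf(snr_db):
            return trial.with_samples(clean.copy())
        if not trial.bursts:
            raise ValueError("finite snr_db requires at least one burst")
        sigma = _noise_sigma(clean, trial.burst_mask(), float(snr_db))
        noisy = clean + rng.normal(0.0, sigma, len(clean))
        return EmgTrial(noisy, trial.fs, trial.bursts, snr_db=float(snr_db))

    # piecewise schedule
    schedule = [((float(t0), float(t1)), float(db)) for (t0, t1), db in snr_db]
    schedule.sort(key=lambda item: item[0][0])
    for (a0, a1), _ in schedule:
        if not a0 < a1:
            raise ValueError(f"empty schedule interval ({a0}, {a1})")
    for ((_, p1), _), ((c0, _), _) in zip(schedule, schedule[1:]):
        if c0 < p1:
            raise ValueError("schedule intervals overlap")
    if not trial.bursts:
        raise ValueError("finite snr_db requires at least one burst")
    mask = trial.burst_mask()
    p_global = float(np.mean(clean[mask] ** 2))
    noisy = clean.copy()
    fs = trial.fs
    for (t0, t1), db in schedule:
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), len(clean))
        seg_mask = mask[i0:i1]
        p_seg = float(np.mean(clean[i0:i1][seg_mask] ** 2)) if seg_mask.any() else p_global
        sigma = math.sqrt(p_seg / 10.0 ** (db / 10.0))
        noisy[i0:i1] += rng.normal(0.0, sigma, i1 - i0)
    return EmgTrial(noisy, trial.fs, trial.bursts, snr_db=schedule)


def condition_signal(
    trial: EmgTrial,
    low: float = 20.0,
    high: float = 500.0,
    order: int = 6,
    zero_phase: bool = True,
) -> EmgTrial:
    """Band-pass condition a trial with a Butterworth filter.

    ``order`` is the overall band-pass order (default 6, i.e. 3 pole pairs).
    Zero-phase (forward-backward) filtering is the default so ground-truth
    onset times are not biased by group delay; set ``zero_phase=False`` for a
    causal, real-time-equivalent variant.
    """
    nyq = trial.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got {low}, {high}")
    if high >= nyq:
        raise ValueError(f"high cut-off {high} Hz must lie below Nyquist {nyq} Hz")
    if order < 2 or order % 2:
        raise ValueError(f"order must be a positive even integer, got {order}")
    sos = sps.butter(order // 2, [low, high], btype="bandpass", fs=trial.fs, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, trial.samples)
    else:
        filtered = sps.sosfilt(sos, trial.samples)
    return trial.with_samples(filtered)
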