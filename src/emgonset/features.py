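"""Mel-subband log-power envelopes.

The raw signal is chopped into overlapping Hanning-windowed frames
(32 ms window, 14 ms hop by default), transformed by FFT, and the bin powers
are grouped into N Mel-spaced subbands.  The subband log energy of frame l in
band n is

    x_l = 10 * log10( (1 / (f_{n+1} - f_n)) * sum_{j=f_n}^{f_{n+1}-1} |Y_{l,j}|^2 )

i.e. the mean bin power in dB, where f_n are the band-edge bin indices.  Each
band's sequence is smoothed with a five-point running median to form the
envelope the detector operates on.

At 2 kHz with a 64-point FFT the eight subbands are the 1-based inclusive bin
groups (1-3), (4-6), (7-9), (10-13), (14-17), (18-22), (23-27), (28-33)
(bin 1 = DC, 31.25 Hz per bin); nominal edges 0, 82.1, 173.8, 276.3, 390.9,
518.8, 661.8, 821.5, 1000 Hz.  At other sampling rates the groups are
recomputed by mapping Mel-spaced edges over 0..min(1000, fs/2) to FFT bins,
which reproduces the canonical groups at 2 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameConfig",
    "SubbandEnvelope",
    "mel_band_bins",
    "frame_signal",
    "subband_log_power",
    "median_smooth",
    "subband_envelope",
]

#: 1-based inclusive FFT-bin groups for fs = 2 kHz, 64-point FFT (bin 1 = DC).
BAND_BINS_2KHZ: tuple[tuple[int, int], ...] = (
    (1, 3), (4, 6), (7, 9), (10, 13), (14, 17), (18, 22), (23, 27), (28, 33),
)

_POWER_FLOOR_REL = 1e-12  # relative to the frame's max bin power
_POWER_FLOOR_ABS = 1e-300


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_band_bins(fs: float, fft_len: int, n_bands: int = 8) -> tuple[tuple[int, int], ...]:
    """Mel-spaced 1-based inclusive FFT-bin groups over 0..min(1000, fs/2) Hz.

    Bin j (1-based) sits at frequency (j-1)*fs/fft_len; band n collects the
    bins with f_edge[n] <= freq < f_edge[n+1], the last band closing at the
    top edge inclusively.
    """
    f_max = min(1000.0, fs / 2.0)
    edges_hz = _mel_to_hz(np.linspace(0.0, float(_hz_to_mel(f_max)), n_bands + 1))
    df = fs / fft_len
    top_bin = int(math.floor(f_max / df)) + 1  # 1-based index of the top edge bin
    groups: list[tuple[int, int]] = []
    lo = 1
    for n in range(n_bands):
        if n < n_bands - 1:
            hi = int(math.ceil(edges_hz[n + 1] / df))  # last bin strictly below edge
        else:
            hi = top_bin
        hi = min(hi, top_bin)
        if hi < lo:
            raise ValueError(
                f"band {n} is empty at fs={fs}, fft_len={fft_len}; too many bands"
            )
        groups.append((lo, hi))
        lo = hi + 1
    return tuple(groups)


@dataclass
class FrameConfig:
    """Framing and subband layout.

    win_ms/hop_ms default to the 32/14 ms analysis grid ("overlapping step"
    read as the frame shift, giving 18 ms overlap).  ``fft_len`` defaults to
    the window length in samples.  ``band_bins`` are 1-based inclusive DFT-bin
    ranges with bin 1 = DC; when None they are resolved per sampling rate
    (the canonical groups at 2 kHz, Mel-derived otherwise).
    """

    win_ms: float = 32.0
    hop_ms: float = 14.0
    window: str = "hann"
    fft_len: int | None = None
    band_bins: tuple[tuple[int, int], ...] | None = None
    band_edges_hz: tuple[float, ...] | None = None
    n_bands: int = 8

    def __post_init__(self) -> None:
        if not self.hop_ms > 0:
            raise ValueError(f"hop_ms must be positive, got {self.hop_ms}")
        if not self.win_ms > self.hop_ms:
            raise ValueError(
                f"win_ms must exceed hop_ms, got win={self.win_ms}, hop={self.hop_ms}"
            )
        if self.band_bins is not None:
            bins = tuple(tuple(b) for b in self.band_bins)
            for (lo, hi) in bins:
                if lo < 1 or hi < lo:
                    raise ValueError(f"invalid bin range ({lo}, {hi})")
            for (_, hi), (lo2, _) in zip(bins, bins[1:]):
                if lo2 <= hi:
                    raise ValueError("band_bins must be disjoint and ascending")
            self.band_bins = bins
            self.n_bands = len(bins)

    def win_samples(self, fs: float) -> int:
        return int(round(self.win_ms * fs / 1000.0))

    def hop_samples(self, fs: float) -> int:
        return int(round(self.hop_ms * fs / 1000.0))

    def resolve_fft_len(self, fs: float) -> int:
        return self.fft_len if self.fft_len is not None else self.win_samples(fs)

    def resolve_band_bins(self, fs: float) -> tuple[tuple[int, int], ...]:
        if self.band_bins is not None:
            return self.band_bins
        fft_len = self.resolve_fft_len(fs)
        if fs == 2000.0 and fft_len == 64 and self.n_bands == 8:
            return BAND_BINS_2KHZ
        return mel_band_bins(fs, fft_len, self.n_bands)


@dataclass
class SubbandEnvelope:
    """Smoothed per-band log-power matrix (frames x bands, dB)."""

    values: np.ndarray
    frame_times_s: np.ndarray
    config: FrameConfig

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def frame_signal(samples: np.ndarray, fs: float, config: FrameConfig | None = None) -> np.ndarray:
    """Split a signal into overlapping Hanning-tapered frames.

    Returns a (n_frames, win) matrix with
    ``n_frames = floor((len - win) / hop) + 1``.
    """
    if config is None:
        config = FrameConfig()
    x = np.asarray(samples, dtype=float)
    win = config.win_samples(fs)
    hop = config.hop_samples(fs)
    if len(x) < win:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {win}-sample window"
        )
    n_frames = (len(x) - win) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[:: hop][:n_frames]
    taper = np.hanning(win)  # symmetric, zero endpoints
    return frames * taper


def subband_log_power(
    frames: np.ndarray, fs: float, config: FrameConfig | None = None
) -> np.ndarray:
    """Per-band mean FFT-bin power in dB for each frame.

    Bin powers are floored at 1e-12 x the frame's maximum bin power before
    the log so all-zero frames yield a finite small value instead of -inf.
    """
    if config is None:
        config = FrameConfig()
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    fft_len = config.resolve_fft_len(fs)
    if fft_len < frames.shape[1]:
        raise ValueError(f"fft_len {fft_len} shorter than frame length {frames.shape[1]}")
    bins = config.resolve_band_bins(fs)
    n_rbins = fft_len // 2 + 1
    for (lo, hi) in bins:
        if hi > n_rbins:
            raise ValueError(
                f"bin range ({lo}, {hi}) exceeds the {n_rbins} available FFT bins"
            )
    power = np.abs(np.fft.rfft(frames, n=fft_len, axis=1)) ** 2
    floor = np.maximum(power.max(axis=1) * _POWER_FLOOR_REL, _POWER_FLOOR_ABS)
    power = np.maximum(power, floor[:, None])
    out = np.empty((frames.shape[0], len(bins)))
    for n, (lo, hi) in enumerate(bins):
        out[:, n] = 10.0 * np.log10(power[:, lo - 1 : hi].mean(axis=1))
    return out


def median_smooth(series: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered running median with shrinking windows at the edges.

    The first/last ``k // 2`` samples use the truncated symmetric window
    (3- then 4-point medians for k = 5), preserving length.
    """
    if k % 2 == 0 or k < 1:
        raise ValueError(f"k must be odd and positive, got {k}")
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n == 0 or k == 1:
        return x.copy()
    h = k // 2
    out = np.empty(n)
    if n >= k:
        out[h : n - h] = np.median(np.lib.stride_tricks.sliding_window_view(x, k), axis=1)
    for i in range(min(h, n)):
        out[i] = np.median(x[: i + h + 1])
        out[n - 1 - i] = np.median(x[n - 1 - i - h :])
    return out


def subband_envelope(
    samples: np.ndarray,
    fs: float,
    config: FrameConfig | None = None,
    median_k: int = 5,
) -> SubbandEnvelope:
    """Full feature path: framing -> subband log power -> median smoothing."""
    if config is None:
        config = FrameConfig()
    frames = frame_signal(samples, fs, config)
    raw = subband_log_power(frames, fs, config)
    smoothed = np.column_stack(
        [median_smooth(raw[:, b], median_k) for b in range(raw.shape[1])]
    )
    hop = config.hop_samples(fs)
    frame_times = np.arange(raw.shape[0]) * hop / fs
    return SubbandEnvelope(values=smoothed, frame_times_s=frame_times, config=config)
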