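"""Signal and result file I/O plus flat key-value configuration.

Supported signal formats: plain text (one sample per line), CSV (column
selected by name or index), and WAV (integer samples rescaled to [-1, 1]).
Detection results are written as diff-stable text tables with six-decimal
numeric fields.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .baselines import BaselineConfig
from .detector import DetectionConfig, DetectionResult
from .features import FrameConfig
from .sgmm import GmmConfig
from .simulate import EmgTrial

__all__ = [
    "read_signal",
    "write_signal",
    "write_results",
    "load_config",
    "build_configs",
]

_INT_SCALE = {
    np.dtype("int16"): 2**15,
    np.dtype("int32"): 2**31,
    np.dtype("uint8"): 2**7,
}


def read_signal(
    path: str | Path,
    fs: float | None = None,
    fmt: str | None = None,
    column: str | int | None = None,
) -> EmgTrial:
    """Read a single-channel signal file into an :class:`EmgTrial`.

    ``fs`` is required for text/CSV input and read from the header for WAV.
    NaN values and blank lines are rejected with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"wav": "wav", ".wav": "wav", ".csv": "csv"}.get(suffix, "text")

    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            raise ValueError(f"{path}: multi-channel WAV not supported")
        scale = _INT_SCALE.get(data.dtype)
        samples = data.astype(float) / scale if scale else data.astype(float)
        if data.dtype == np.dtype("uint8"):
            samples -= 1.0
        return EmgTrial(samples=samples, fs=float(rate))

    if fs is None:
        raise ValueError(f"{path}: sampling rate fs is required for {fmt} input")

    if fmt == "csv":
        frame = pd.read_csv(path)
        if column is None:
            if frame.shape[1] != 1:
                raise ValueError(
                    f"{path}: multi-column CSV requires an explicit column selection"
                )
            series = frame.iloc[:, 0]
        elif isinstance(column, int) or str(column).isdigit():
            series = frame.iloc[:, int(column)]
        else:
            if column not in frame.columns:
                raise ValueError(f"{path}: no column named {column!r}")
            series = frame[column]
        values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if len(bad):
            raise ValueError(f"{path}: unparseable value at data row {bad[0] + 1}")
        return EmgTrial(samples=values, fs=float(fs))

    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                raise ValueError(f"{path}: blank line at line {lineno}")
            try:
                value = float(text)
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable line {lineno}: {text!r}") from exc
            if not np.isfinite(value):
                raise ValueError(f"{path}: non-finite value at line {lineno}")
            samples.append(value)
    return EmgTrial(samples=np.asarray(samples), fs=float(fs))


def write_signal(trial: EmgTrial, path: str | Path, fmt: str | None = None) -> None:
    """Write samples as one-per-line text or 16-bit-float-free WAV."""
    path = Path(path)
    if fmt is None:
        fmt = "wav" if path.suffix.lower() == ".wav" else "text"
    if fmt == "wav":
        wavfile.write(path, int(round(trial.fs)), trial.samples.astype(np.float32))
    else:
        np.savetxt(path, trial.samples, fmt="%.9g")


def write_truth(trial: EmgTrial, path: str | Path) -> None:
    """Ground-truth bursts as TSV (onset_s, offset_s, gain)."""
    rows = [
        {"onset_s": b.onset_s, "offset_s": b.offset_s, "gain": b.gain}
        for b in trial.bursts
    ]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "gain"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_results(result: DetectionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write segments TSV, votes CSV, probability-map CSV and thresholds CSV.

    Returns a mapping of logical name to path.  Numeric fields use six
    decimals so outputs are diff-stable across platforms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    seg = pd.DataFrame(result.segments, columns=["onset_s", "offset_s"])
    paths["segments"] = out_dir / "segments.tsv"
    seg.to_csv(paths["segments"], sep="\t", index=False, float_format="%.6f")

    votes = pd.DataFrame(
        {"frame_time_s": result.frame_times_s, "votes": result.votes}
    )
    paths["votes"] = out_dir / "votes.csv"
    votes.to_csv(paths["votes"], index=False, float_format="%.6f")

    n_bands = result.prob_map.shape[1]
    band_cols = [f"band_{b + 1}" for b in range(n_bands)]
    for name, matrix in (("prob_map", result.prob_map), ("thresholds", result.thresholds)):
        frame = pd.DataFrame(matrix, columns=band_cols)
        frame.insert(0, "frame_time_s", result.frame_times_s)
        paths[name] = out_dir / f"{name}.csv"
        frame.to_csv(paths[name], index=False, float_format="%.6f")
    return paths


_CONFIG_KEYS = {
    # frame
    "win_ms": float, "hop_ms": float, "n_bands": int,
    # gmm
    "alpha": float, "delta": float, "epsilon": float, "m_init": int,
    "em_tol": float, "em_max_iter": int,
    # detection
    "vote_threshold": int, "min_segment_ms": float, "min_gap_ms": float,
    "median_k": int,
    # baselines
    "baseline_start_s": float, "baseline_end_s": float,
    "amp_k": float, "tkeo_k": float, "smoothing_ms": float,
    "threshold_form": str, "bonato_zeta": float, "bonato_m": int,
    "bonato_r0": int, "bonato_min_active_ms": float,
}


def load_config(path: str | Path) -> dict:
    """Load and validate a flat key-value (YAML) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    out = {}
    for key, value in raw.items():
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}: unknown config key {key!r}")
        caster = _CONFIG_KEYS[key]
        try:
            out[key] = caster(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid value for {key!r}: {value!r}") from exc
    return out


def build_configs(options: dict) -> tuple[DetectionConfig, BaselineConfig]:
    """Build detection and baseline configs from flat config options."""
    frame_kwargs = {k: options[k] for k in ("win_ms", "hop_ms", "n_bands") if k in options}
    gmm_kwargs = {
        k: options[k]
        for k in ("alpha", "delta", "epsilon", "m_init", "em_tol", "em_max_iter")
        if k in options
    }
    det_kwargs = {
        k: options[k]
        for k in ("vote_threshold", "min_segment_ms", "min_gap_ms", "median_k")
        if k in options
    }
    detection = DetectionConfig(
        frame=FrameConfig(**frame_kwargs), gmm=GmmConfig(**gmm_kwargs), **det_kwargs
    )
    base_kwargs = {
        k: options[k]
        for k in (
            "amp_k", "tkeo_k", "smoothing_ms", "threshold_form", "bonato_zeta",
            "bonato_m", "bonato_r0", "bonato_min_active_ms",
        )
        if k in options
    }
    if "baseline_start_s" in options or "baseline_end_s" in options:
        base_kwargs["baseline_window_s"] = (
            options.get("baseline_start_s", 0.0),
            options.get("baseline_end_s", 0.5),
        )
    baseline = BaselineConfig(**base_kwargs)
    return detection, baseline
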