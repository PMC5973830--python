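"""Sensor-space epoch container and deterministic pre-decoding transforms.

An epoch set is the universal currency of the pipeline: a ``trials x sensors
x samples`` array of field strengths time-locked to an event (stimulus or
retro-cue onset at t = 0), with per-trial class labels (0 = "house",
1 = "face" by convention) and a condition tag (``perception``, ``imagery``
or ``eyetrack``).

Transforms never modify their input; they return new :class:`EpochsArray`
instances with metadata propagated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "TimeWindow",
    "EpochsArray",
    "baseline_correct",
    "sliding_average",
    "downsample",
    "crop",
    "low_pass",
]

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval [start_s, end_s) in seconds relative to onset."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"TimeWindow requires start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of samples falling inside the window."""
        return (times >= self.start_s - _TIME_TOL) & (times < self.end_s - _TIME_TOL)

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EpochsArray:
    """Trials x sensors x samples of field strength with trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_samples)
        Field strength in arbitrary units.
    labels : ndarray of int, shape (n_trials,)
        Class identifier per trial, 0 or 1 (1 = "face").
    times : ndarray, shape (n_samples,)
        Sample instants in seconds relative to event onset; strictly
        increasing with spacing 1/fs.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered sensor names.
    condition : str
        One of "perception", "imagery", "eyetrack".
    subject_id : str
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    condition: str = "perception"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not self.channels:
            self.channels = [f"MEG{i:03d}" for i in range(self.data.shape[1])]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, sensors, samples), got {self.data.ndim}-D")
        n_trials, n_sensors, n_samples = self.data.shape
        if self.labels.shape != (n_trials,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match {n_trials} trials"
            )
        if self.times.shape != (n_samples,):
            raise ValueError(
                f"times length {self.times.shape} does not match {n_samples} samples"
            )
        if len(self.channels) != n_sensors:
            raise ValueError("channels length does not match sensor axis")
        if n_samples > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.fs) > _TIME_TOL):
                raise ValueError("times spacing inconsistent with fs")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0 or 1")

    # -- convenience ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def require_both_classes(self) -> None:
        present = np.unique(self.labels)
        if not (0 in present and 1 in present):
            raise ValueError(f"both classes required for training; found labels {present}")

    def copy_with(self, **kw) -> "EpochsArray":
        out = replace(self, **kw)
        return out

    # -- serialization -------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write the epoch set as a directory: flat binary data + JSON metadata."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "data.npy", self.data)
        meta = {
            "labels": self.labels.tolist(),
            "times": self.times.tolist(),
            "fs": self.fs,
            "channels": list(self.channels),
            "condition": self.condition,
            "subject_id": self.subject_id,
        }
        (d / "meta.json").write_text(json.dumps(meta, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "EpochsArray":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        data = np.load(d / "data.npy")
        return cls(
            data=data,
            labels=np.asarray(meta["labels"]),
            times=np.asarray(meta["times"]),
            fs=meta["fs"],
            channels=meta["channels"],
            condition=meta["condition"],
            subject_id=meta["subject_id"],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (one row per trial x channel), for small fixtures."""
        n_trials, n_sensors, _ = self.data.shape
        rows = []
        for i in range(n_trials):
            for j in range(n_sensors):
                rows.append(
                    {
                        "trial": i,
                        "label": int(self.labels[i]),
                        "channel": self.channels[j],
                        **{f"t{k}": self.data[i, j, k] for k in range(self.n_samples)},
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochsArray, window: TimeWindow) -> EpochsArray:
    """Subtract the per-trial, per-channel mean over ``window`` from all samples."""
    mask = window.mask(epochs.times)
    if not mask.any():
        raise ValueError(
            f"baseline window [{window.start_s}, {window.end_s}) contains no samples "
            f"of the epoch (times span [{epochs.times[0]}, {epochs.times[-1]}])"
        )
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def _boxcar_length(window_ms: float, fs: float) -> int:
    n = int(round(window_ms / 1000.0 * fs))
    n = max(n, 1)
    if n % 2 == 0:  # force odd so "centered" is exact
        n += 1
    return n


def sliding_average(epochs: EpochsArray, window_ms: float) -> EpochsArray:
    """Centered boxcar smoothing per channel and trial.

    Window length in samples is ``round(window_ms/1000 * fs)``, forced odd.
    Epoch edges use the truncated window (mean of the available samples); no
    data is fabricated beyond the borders.
    """
    if window_ms <= 0:
        raise ValueError(f"window_ms must be positive, got {window_ms}")
    n = _boxcar_length(window_ms, epochs.fs)
    n_samples = epochs.n_samples
    if n >= 2 * n_samples:
        raise ValueError(f"smoothing window of {n} samples too long for {n_samples}-sample epoch")
    if n == 1:
        return epochs.copy_with(data=epochs.data.copy())
    half = n // 2
    csum = np.concatenate(
        [np.zeros(epochs.data.shape[:2] + (1,)), np.cumsum(epochs.data, axis=2)], axis=2
    )
    idx = np.arange(n_samples)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n_samples)
    counts = (hi - lo).astype(np.float64)
    out = (csum[:, :, hi] - csum[:, :, lo]) / counts
    return epochs.copy_with(data=out)


def downsample(epochs: EpochsArray, target_fs: float) -> EpochsArray:
    """Anti-alias low-pass then decimate to ``target_fs``.

    The decimation factor fs/target_fs must be an integer. The anti-alias
    filter is a zero-phase Butterworth with cutoff 0.4 * target_fs.
    """
    factor_f = epochs.fs / target_fs
    factor = int(round(factor_f))
    if factor < 1 or abs(factor_f - factor) > 1e-9:
        raise ValueError(
            f"fs/target_fs must be an integer decimation factor; got {epochs.fs}/{target_fs}"
        )
    if factor == 1:
        return epochs.copy_with(data=epochs.data.copy())
    sos = sp_signal.butter(8, 0.4 * target_fs, btype="low", fs=epochs.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, epochs.data, axis=2)
    n_out = epochs.n_samples // factor
    keep = np.arange(n_out) * factor
    return epochs.copy_with(
        data=np.ascontiguousarray(filtered[:, :, keep]),
        times=epochs.times[keep].copy(),
        fs=target_fs,
    )


def crop(epochs: EpochsArray, window: TimeWindow) -> EpochsArray:
    """Restrict samples to [start, end); times stay relative to the original onset."""
    mask = window.mask(epochs.times)
    if not mask.any():
        raise ValueError(
            f"crop window [{window.start_s}, {window.end_s}) leaves no samples"
        )
    return epochs.copy_with(
        data=np.ascontiguousarray(epochs.data[:, :, mask]),
        times=epochs.times[mask].copy(),
    )


def low_pass(epochs: EpochsArray, cutoff_hz: float, order: int = 4) -> EpochsArray:
    """Zero-phase Butterworth low-pass (used on imagery segments before source analysis)."""
    if not 0 < cutoff_hz < epochs.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist)")
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=epochs.fs, output="sos")
    return epochs.copy_with(data=sp_signal.sosfiltfilt(sos, epochs.data, axis=2))
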