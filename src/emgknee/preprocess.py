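"""Raw sEMG + angle series -> aligned windowed RMS features and labels.

The chain is the standard surface-EMG front end: zero-phase 10-400 Hz
bandpass plus a 50 Hz notch (2 Hz bandwidth), full-wave rectification,
overlapped windowing (180 ms windows sharing 80 ms, i.e. a 100 ms stride),
per-window per-channel RMS, and min-max normalization of each channel to
[0, 1] fitted on training data.  Each EMG window is labelled with the mean
of the 10 angle samples (100 ms at 100 Hz) centred on the window centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "NormParams",
    "FeatureDataset",
    "bandpass_notch",
    "rectify",
    "window_slices",
    "rms_feature",
    "average_angle",
    "raw_rms_features",
    "build_dataset",
]


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass corner frequencies and notch location, Hz."""

    band_low: float = 10.0
    band_high: float = 400.0
    notch_center: float = 50.0
    notch_bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if not self.band_low < self.notch_center < self.band_high:
            raise ValueError("notch must lie inside the passband")
        if self.notch_bandwidth <= 0.0:
            raise ValueError("notch_bandwidth must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry in seconds plus the angle-label width."""

    window_len: float = 0.180
    overlap: float = 0.080
    angle_window_n: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < self.window_len:
            raise ValueError("require 0 <= overlap < window_len")
        if self.angle_window_n < 1:
            raise ValueError("angle_window_n must be >= 1")

    @property
    def step(self) -> float:
        return self.window_len - self.overlap


@dataclass(frozen=True)
class NormParams:
    """Per-channel raw-RMS minima and maxima fitted on training data."""

    lo: np.ndarray
    hi: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        x = (raw - self.lo) / span
        # out-of-range test data is clipped before being clamped into [0, 1]
        return np.clip(np.clip(x, -0.05, 1.05), 0.0, 1.0)


@dataclass
class FeatureDataset:
    """Aligned per-window features and angle labels.

    ``features`` is (n_windows, 4), min-max normalized RMS per channel;
    ``labels`` is the windowed mean angle in degrees; ``window_times`` are
    the window-centre times in seconds.
    """

    features: np.ndarray
    labels: np.ndarray
    norm_params: NormParams
    window_times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align 1:1")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "FeatureDataset":
        return FeatureDataset(
            self.features[idx], self.labels[idx], self.norm_params, self.window_times[idx]
        )

    def split(self, fraction: float) -> Tuple["FeatureDataset", "FeatureDataset"]:
        """Chronological head/tail split (no shuffling: windows overlap)."""
        k = int(round(fraction * len(self)))
        return self.subset(slice(0, k)), self.subset(slice(k, None))


def bandpass_notch(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase bandpass + notch; same shape out as in.

    4th-order Butterworth bandpass and a 2nd-order IIR notch, each applied
    forward-backward so the output is phase-neutral.
    """
    if fs <= 2.0 * spec.band_high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    x = np.asarray(x, dtype=float)
    one_dim = x.ndim == 1
    x2 = np.atleast_2d(x)
    sos = sps.butter(4, [spec.band_low, spec.band_high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x2, axis=-1)
    b, a = sps.iirnotch(spec.notch_center, spec.notch_center / spec.notch_bandwidth, fs=fs)
    y = sps.filtfilt(b, a, y, axis=-1)
    return y[0] if one_dim else y


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def window_slices(n_samples: int, fs: float, spec: WindowSpec = WindowSpec()) -> List[Tuple[int, int]]:
    """Half-open [start, end) index pairs for the overlapped windows.

    Window and stride are ``round(seconds * fs)`` samples (347 and 193 at
    1928 Hz); a trailing partial window is dropped.
    """
    win = int(round(spec.window_len * fs))
    stride = int(round(spec.step * fs))
    if stride < 1:
        raise ValueError("window stride rounds to zero samples")
    if n_samples < win:
        raise ValueError("signal shorter than one analysis window")
    n_win = (n_samples - win) // stride + 1
    return [(i * stride, i * stride + win) for i in range(n_win)]


def rms_feature(window: np.ndarray) -> float:
    """Root-mean-square amplitude of one window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(window**2)))


def average_angle(window: np.ndarray, n: int = 10) -> float:
    """Mean of an ``n``-sample angle window, degrees."""
    window = np.asarray(window, dtype=float)
    if window.size != n:
        raise ValueError(f"angle window must have exactly {n} samples")
    return float(np.mean(window))


def raw_rms_features(
    emg: np.ndarray,
    fs: float,
    filter_spec: FilterSpec = FilterSpec(),
    window_spec: WindowSpec = WindowSpec(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Unnormalized windowed RMS features and window-centre times.

    Filter -> rectify -> window -> per-channel RMS; returns the
    ``(n_windows, n_channels)`` matrix and centre times in seconds.
    """
    filtered = bandpass_notch(emg, fs, filter_spec)
    rect = rectify(filtered)
    slices = window_slices(rect.shape[-1], fs, window_spec)
    feats = np.array([[rms_feature(ch[s:e]) for ch in rect] for s, e in slices])
    centers = np.array([(s + e - 1) / 2.0 / fs for s, e in slices])
    return feats, centers


def build_dataset(
    emg: np.ndarray,
    angle: np.ndarray,
    fs_emg: float,
    fs_angle: float,
    filter_spec: FilterSpec = FilterSpec(),
    window_spec: WindowSpec = WindowSpec(),
    norm_params: Optional[NormParams] = None,
) -> FeatureDataset:
    """Full front end: filter, rectify, window, RMS, label, normalize.

    If ``norm_params`` is given it is applied as-is (test data); otherwise
    per-channel min-max parameters are fitted on this data (training data).
    The EMG and angle series must cover the same time span to within one
    analysis window.
    """
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    angle = np.asarray(angle, dtype=float)
    span_emg = emg.shape[-1] / fs_emg
    span_angle = angle.size / fs_angle
    if abs(span_emg - span_angle) > window_spec.window_len:
        raise ValueError(
            f"EMG span ({span_emg:.3f} s) and angle span ({span_angle:.3f} s) "
            "differ by more than one analysis window"
        )

    raw, centers = raw_rms_features(emg, fs_emg, filter_spec, window_spec)

    if norm_params is None:
        norm_params = NormParams(lo=raw.min(axis=0), hi=raw.max(axis=0))
    features = norm_params.apply(raw)

    n_lab = window_spec.angle_window_n
    labels = np.empty(len(centers))
    for i, tc in enumerate(centers):
        start = int(round(tc * fs_angle - n_lab / 2.0))
        start = min(max(start, 0), angle.size - n_lab)
        labels[i] = average_angle(angle[start : start + n_lab], n_lab)

    return FeatureDataset(features, labels, norm_params, centers)
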