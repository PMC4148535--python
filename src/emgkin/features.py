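"""Windowed time-domain EMG features and time alignment of regressor inputs.

The classical baseline feature set computed per sliding window and channel:

* MAV — mean absolute value, (1/N) sum |x_i|
* WL  — waveform length, sum |x_{i+1} - x_i|
* WA  — Willison amplitude, count of |x_{i+1} - x_i| > threshold
* VAR — sample variance, (1/(N-1)) sum (x_i - mean)^2

Windows default to 200 ms length with a 25 ms step (40 Hz frame rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EmgRecording, NormalizedKinematics

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "sliding_windows",
    "mav",
    "wl",
    "wa",
    "var",
    "extract_td_features",
    "align_targets",
    "default_wa_threshold",
]

TD_FEATURE_NAMES = ("MAV", "WL", "WA", "VAR")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds relative to a source rate."""

    length: float = 0.200
    step: float = 0.025
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.length:
            raise ValueError("require 0 < step <= length")
        if self.length * self.fs < 2:
            raise ValueError("window must contain at least 2 samples")

    @property
    def length_samples(self) -> int:
        return int(round(self.length * self.fs))

    @property
    def step_samples(self) -> int:
        return int(round(self.step * self.fs))


@dataclass
class FeatureMatrix:
    """Time-aligned regressor inputs: frames x (channels * n_features)."""

    values: np.ndarray
    frame_times: np.ndarray
    feature_labels: list[str]
    source_kind: str = "td"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.values.shape[0] != self.frame_times.size:
            raise ValueError("frame count mismatch")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels length mismatch")


def sliding_windows(n_samples: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, end) index pairs; last partial window dropped."""
    L, S = spec.length_samples, spec.step_samples
    if n_samples < L:
        raise ValueError(f"series of {n_samples} samples shorter than one window ({L})")
    n_frames = (n_samples - L) // S + 1
    return [(i * S, i * S + L) for i in range(n_frames)]


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a window."""
    return float(np.mean(np.abs(x)))


def wl(x: np.ndarray) -> float:
    """Waveform length: cumulative absolute first difference."""
    return float(np.sum(np.abs(np.diff(x))))


def wa(x: np.ndarray, threshold: float) -> int:
    """Willison amplitude: count of sample-to-sample jumps above threshold."""
    return int(np.sum(np.abs(np.diff(x)) > threshold))


def var(x: np.ndarray) -> float:
    """Unbiased sample variance (N-1 denominator)."""
    return float(np.var(x, ddof=1))


def default_wa_threshold(rec: EmgRecording, rest_slice: slice | None = None) -> np.ndarray:
    """Per-channel Willison-amplitude threshold.

    Twice the median sample-to-sample absolute difference of a rest
    segment when one is given; otherwise 1% of the channel's max-abs.
    """
    if rest_slice is not None:
        seg = rec.samples[:, rest_slice]
        return 2.0 * np.median(np.abs(np.diff(seg, axis=1)), axis=1)
    return 0.01 * np.max(np.abs(rec.samples), axis=1)


def extract_td_features(
    rec: EmgRecording,
    spec: WindowSpec | None = None,
    wa_threshold: np.ndarray | float | None = None,
) -> FeatureMatrix:
    """Compute the four TD features per channel over sliding windows.

    Features are evaluated on the raw (unrectified, unfiltered) signal at
    its native rate.  Frame times mark the window end in seconds.
    """
    spec = spec or WindowSpec(fs=rec.fs)
    if abs(spec.fs - rec.fs) > 1e-9:
        raise ValueError("WindowSpec.fs must match the recording rate")
    if wa_threshold is None:
        wa_threshold = default_wa_threshold(rec)
    thr = np.broadcast_to(np.atleast_1d(np.asarray(wa_threshold, float)),
                          (rec.n_channels,))
    wins = sliding_windows(rec.n_samples, spec)
    rows = np.empty((len(wins), rec.n_channels * 4))
    for f, (s, e) in enumerate(wins):
        w = rec.samples[:, s:e]
        dw = np.abs(np.diff(w, axis=1))
        rows[f, 0::4] = np.mean(np.abs(w), axis=1)
        rows[f, 1::4] = np.sum(dw, axis=1)
        rows[f, 2::4] = np.sum(dw > thr[:, None], axis=1)
        rows[f, 3::4] = np.var(w, axis=1, ddof=1)
    labels = [
        f"{ch}_{feat}" for ch in rec.channel_labels for feat in TD_FEATURE_NAMES
    ]
    times = np.array([e / rec.fs for _, e in wins])
    return FeatureMatrix(rows, times, labels, source_kind="td")


def align_targets(
    features: FeatureMatrix, theta: NormalizedKinematics
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each feature frame with the nearest kinematic sample in time.

    Returns (inputs, targets) with one row per feature frame; targets are
    DOFs x frames transposed to frames x DOFs.
    """
    kin_times = np.arange(theta.values.shape[1]) / theta.fs
    if features.frame_times[0] > kin_times[-1] or features.frame_times[-1] < kin_times[0]:
        raise ValueError("feature frames and kinematics do not overlap in time")
    idx = np.clip(
        np.round(features.frame_times * theta.fs).astype(int),
        0,
        theta.values.shape[1] - 1,
    )
    return features.values, theta.values[:, idx].T


def envelope_feature_matrix(values: np.ndarray, fs: float,
                            channel_labels: list[str],
                            source_kind: str = "envelope") -> FeatureMatrix:
    """Wrap a channels x time series as a per-sample FeatureMatrix."""
    values = np.atleast_2d(values)
    times = np.arange(values.shape[1]) / fs
    return FeatureMatrix(values.T, times, list(channel_labels), source_kind)
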