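"""Raw-signal conditioning: EMG envelopes and marker-derived joint angles.

The EMG chain mirrors the standard myocontrol preprocessing pipeline:
full-wave rectification, normalization by the peak rectified value (MVC),
zero-phase low-pass filtering at 4 Hz, and decimation to the kinematic
sampling rate (200 Hz).  Joint angles are computed from three markers per
joint with the convention that a fully straight segment reads 0 deg and
flexion is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "EmgRecording",
    "EnvelopeSeries",
    "MarkerTrajectories",
    "JointAngleSeries",
    "NormalizedKinematics",
    "compute_mvc",
    "rectify_normalize",
    "lowpass_zero_phase",
    "downsample",
    "preprocess_emg",
    "compute_joint_angles",
    "normalize_angles",
    "denormalize_angles",
    "EDGE_TRANSIENT_S",
]

#: Duration flagged at each end of a trial as filter start-up transient.
EDGE_TRANSIENT_S = 0.5


@dataclass
class EmgRecording:
    """Multi-channel raw surface EMG.

    Parameters
    ----------
    samples : ndarray, shape (channels, time)
        Raw signal in arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One muscle name per channel.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EnvelopeSeries:
    """Normalized low-frequency EMG envelopes, values in [0, 1]."""

    values: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.values.shape[0])]


@dataclass
class MarkerTrajectories:
    """3-D marker positions, millimetres.

    positions has shape (markers, time, 3).
    """

    positions: np.ndarray
    fs: float
    marker_labels: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (markers, time, 3)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.marker_labels) != self.positions.shape[0]:
            raise ValueError("marker_labels length mismatch")
        if not np.isfinite(self.positions).all():
            raise ValueError("marker trajectories contain missing/non-finite frames")


@dataclass
class JointAngleSeries:
    """Finger joint angles in degrees, one row per degree of freedom."""

    angles: np.ndarray
    dof_labels: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if len(self.dof_labels) != self.angles.shape[0]:
            raise ValueError("dof_labels length mismatch")
        if len(set(self.dof_labels)) != len(self.dof_labels):
            raise ValueError("dof_labels must be unique")
        if not np.isfinite(self.angles).all():
            raise ValueError("angles contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class NormalizedKinematics:
    """Joint angles mapped to [0, 1] with the training-set min/max per DOF."""

    values: np.ndarray
    dof_labels: list[str]
    fs: float
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)


def compute_mvc(recordings: list[EmgRecording] | EmgRecording) -> np.ndarray:
    """Per-channel maximum rectified value over all provided trials.

    The maximum absolute sample over every recording serves as the
    maximum-voluntary-contraction (MVC) reference for normalization.
    """
    if isinstance(recordings, EmgRecording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("at least one recording is required")
    n_ch = recordings[0].n_channels
    for rec in recordings:
        if rec.n_channels != n_ch:
            raise ValueError("channel count differs across recordings")
    mvc = np.max(
        [np.max(np.abs(rec.samples), axis=1) for rec in recordings], axis=0
    )
    zero = np.flatnonzero(mvc <= 0)
    if zero.size:
        labels = [recordings[0].channel_labels[i] for i in zero]
        raise ValueError(f"all-zero channel(s) {labels}: cannot normalize")
    return mvc


def rectify_normalize(rec: EmgRecording, mvc: np.ndarray | float) -> EmgRecording:
    """Full-wave rectify and divide each channel by its MVC value."""
    mvc = np.atleast_1d(np.asarray(mvc, dtype=float))
    if mvc.size == 1:
        mvc = np.full(rec.n_channels, mvc.item())
    if mvc.size != rec.n_channels:
        raise ValueError("mvc length must match channel count")
    if np.any(mvc <= 0):
        raise ValueError("mvc must be strictly positive per channel")
    return EmgRecording(
        samples=np.abs(rec.samples) / mvc[:, None],
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def lowpass_zero_phase(
    x: np.ndarray, fs: float, cutoff: float, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The forward-backward pass doubles the effective magnitude order and
    cancels the phase, so a slow sinusoid passes with no lag.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2)={fs / 2}, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate a band-limited signal by an integer factor (no extra filter)."""
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {factor}")
    return np.asarray(x, dtype=float)[..., :: int(round(factor))]


def preprocess_emg(
    rec: EmgRecording,
    mvc: np.ndarray | float,
    cutoff: float = 4.0,
    fs_out: float = 200.0,
) -> EnvelopeSeries:
    """Rectify, MVC-normalize, 4 Hz zero-phase low-pass, decimate to 200 Hz.

    Small negative overshoot produced by low-pass filtering a rectified
    signal is clipped to 0; values are clipped to [0, 1] overall.
    """
    rn = rectify_normalize(rec, mvc)
    filt = lowpass_zero_phase(rn.samples, rec.fs, cutoff)
    dec = downsample(filt, rec.fs, fs_out)
    return EnvelopeSeries(
        values=np.clip(dec, 0.0, 1.0), fs=fs_out, channel_labels=list(rec.channel_labels)
    )


def compute_joint_angles(
    markers: MarkerTrajectories, skeleton: dict[str, tuple[str, str, str]]
) -> JointAngleSeries:
    """Joint flexion angles from marker triplets.

    For each joint the angle is 180 deg minus the interior angle at the
    middle marker between the two bone vectors: collinear markers (straight
    finger) give 0 deg, flexion is positive, hyperextension negative.
    """
    idx = {lab: i for i, lab in enumerate(markers.marker_labels)}
    labels, rows = [], []
    for joint, (a, b, c) in skeleton.items():
        pa, pb, pc = (markers.positions[idx[m]] for m in (a, b, c))
        v1 = pa - pb
        v2 = pc - pb
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        bad = np.flatnonzero((n1 < 1e-12) | (n2 < 1e-12))
        if bad.size:
            raise ValueError(
                f"joint {joint}: coincident markers at frame {bad[0]}"
            )
        cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
        rows.append(180.0 - np.degrees(np.arccos(cosang)))
        labels.append(joint)
    return JointAngleSeries(np.array(rows), labels, markers.fs)


def preprocess_angles(angles: JointAngleSeries, cutoff: float = 10.0,
                      order: int = 2) -> JointAngleSeries:
    """Zero-phase low-pass of measured joint angles (default 10 Hz).

    Removes capture noise and jitter well above the <= 2 Hz band of
    voluntary finger movement before normalization and regression.
    """
    return JointAngleSeries(
        lowpass_zero_phase(angles.angles, angles.fs, cutoff, order),
        list(angles.dof_labels),
        angles.fs,
    )


def normalize_angles(
    angles: JointAngleSeries,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> NormalizedKinematics:
    """Scale each DOF to [0, 1] with (x - min) / (max - min).

    `stats` are the per-DOF (min, max) learned on TRAINING data; test data
    may exceed [0, 1] slightly and is not clipped.  When omitted, the
    min/max of `angles` itself are used (training fit).
    """
    if stats is None:
        mins = angles.angles.min(axis=1)
        maxs = angles.angles.max(axis=1)
    else:
        mins, maxs = (np.asarray(s, dtype=float) for s in stats)
    flat = np.flatnonzero(maxs <= mins)
    if flat.size:
        raise ValueError(
            f"DOF {angles.dof_labels[flat[0]]}: max == min, cannot normalize"
        )
    values = (angles.angles - mins[:, None]) / (maxs - mins)[:, None]
    return NormalizedKinematics(
        values=values,
        dof_labels=list(angles.dof_labels),
        fs=angles.fs,
        mins=mins,
        maxs=maxs,
    )


def denormalize_angles(norm: NormalizedKinematics) -> JointAngleSeries:
    """Inverse of :func:`normalize_angles` on its domain."""
    angles = norm.values * (norm.maxs - norm.mins)[:, None] + norm.mins[:, None]
    return JointAngleSeries(angles, list(norm.dof_labels), norm.fs)


def edge_mask(n_samples: int, fs: float, margin_s: float = EDGE_TRANSIENT_S) -> np.ndarray:
    """Boolean mask that is False in the first/last `margin_s` seconds."""
    m = int(round(margin_s * fs))
    mask = np.ones(n_samples, dtype=bool)
    if 2 * m >= n_samples:
        warnings.warn("series shorter than twice the edge margin; no mask applied")
        return mask
    mask[:m] = False
    mask[n_samples - m :] = False
    return mask
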