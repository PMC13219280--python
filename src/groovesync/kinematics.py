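"""Marker-trajectory kinematics: from 11-marker motion capture to the neck-angle signal.

The processing chain mirrors standard optical motion-capture practice for
head/neck movement analysis:

1. trim the recording to the stimulus window (trigger-aligned),
2. zero-phase low-pass filter the marker coordinates (4th-order Butterworth,
   5 Hz cutoff, applied forward and backward),
3. compute joint centers (neck, shoulder, thoracolumbar) from marker geometry,
4. express the head-segment orientation relative to the torso segment as three
   rotation components (flexion, lateral bending, axial rotation),
5. collapse the three components into a one-dimensional angular-magnitude
   series (Euclidean norm) for synchrony analysis.

Positions are in metres, angles in degrees, sample indexing is 0-based and
time is ``index / sampling_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

#: Canonical marker set: head top, ears, sternum, acromia, lower ribs, spine.
MARKER_NAMES: tuple[str, ...] = (
    "head_top",
    "ear_L",
    "ear_R",
    "sternum_up",
    "acromion_L",
    "acromion_R",
    "rib_low_L",
    "rib_low_R",
    "C7",
    "T8",
    "T12",
)

#: Head-segment markers: rigidly attached to the skull, they move with the head.
HEAD_MARKERS: tuple[str, ...] = ("head_top", "ear_L", "ear_R")


class MissingMarkerError(KeyError):
    """A required anatomical marker is absent from the series or template."""


class GapTooLongError(ValueError):
    """A marker dropout exceeds the interpolation limit; the trial is rejected."""


@dataclass
class MarkerFrameSeries:
    """Time-indexed 3-D positions of the 11 anatomical markers for one trial.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, n_markers, 3)`` in metres.
    sampling_rate
        Sampling frequency in Hz.
    markers
        Marker names, one per second-axis slot (defaults to the canonical set).

    Raw recordings may contain NaN gaps; :func:`fill_gaps` must be applied
    before any geometric computation.
    """

    positions: np.ndarray
    sampling_rate: float
    markers: tuple[str, ...] = MARKER_NAMES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (n_frames, n_markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.markers):
            raise ValueError(
                f"{self.positions.shape[1]} marker slots but {len(self.markers)} names"
            )
        missing = set(MARKER_NAMES) - set(self.markers)
        if missing:
            raise MissingMarkerError(f"missing markers: {sorted(missing)}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def marker(self, name: str) -> np.ndarray:
        """Return the ``(n_frames, 3)`` trajectory of one named marker."""
        try:
            idx = self.markers.index(name)
        except ValueError as exc:
            raise MissingMarkerError(name) from exc
        return self.positions[:, idx, :]


@dataclass
class JointCenters:
    """Per-frame neck, shoulder and thoracolumbar joint-center positions (metres)."""

    neck: np.ndarray
    shoulder: np.ndarray
    thoracolumbar: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.neck)
        if not (len(self.shoulder) == len(self.thoracolumbar) == n):
            raise ValueError("joint-center arrays must have equal lengths")


@dataclass
class AngleSeries:
    """One-dimensional neck angular-magnitude series, degrees, non-negative."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle values must be finite")
        if np.any(self.values < -1e-9):
            raise ValueError("angle magnitude must be non-negative")
        self.values = np.maximum(self.values, 0.0)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def fill_gaps(series: MarkerFrameSeries, max_gap: int = 10) -> MarkerFrameSeries:
    """Linearly interpolate NaN dropouts of at most ``max_gap`` samples.

    Longer gaps (including leading/trailing runs) reject the trial by raising
    :class:`GapTooLongError`.
    """
    pos = series.positions.copy()
    n = pos.shape[0]
    flat = pos.reshape(n, -1)
    idx = np.arange(n)
    for col in range(flat.shape[1]):
        x = flat[:, col]
        bad = ~np.isfinite(x)
        if not bad.any():
            continue
        if bad.all():
            raise GapTooLongError("marker coordinate entirely missing")
        # run-length encode the gaps
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > max_gap:
                raise GapTooLongError(
                    f"gap of {stop - start} samples exceeds limit {max_gap}"
                )
        good = ~bad
        flat[bad, col] = np.interp(idx[bad], idx[good], x[good])
    return replace(series, positions=flat.reshape(pos.shape))


def trim_to_stimulus(
    series: MarkerFrameSeries, trigger_sample: int, duration_s: float
) -> MarkerFrameSeries:
    """Cut the recording to the stimulus window starting at the trigger sample."""
    if trigger_sample < 0:
        raise ValueError("trigger_sample must be non-negative")
    n_out = round(duration_s * series.sampling_rate)
    if n_out <= 0:
        raise ValueError("duration must be positive")
    if trigger_sample + n_out > series.n_frames:
        raise ValueError(
            f"window [{trigger_sample}, {trigger_sample + n_out}) exceeds "
            f"recording length {series.n_frames}"
        )
    return replace(series, positions=series.positions[trigger_sample : trigger_sample + n_out])


def lowpass_zero_phase(series, cutoff_hz: float = 5.0, order: int = 4, sampling_rate=None):
    """Zero-phase low-pass Butterworth filter (forward-backward application).

    Accepts a :class:`MarkerFrameSeries`, an :class:`AngleSeries` or a plain
    array (then ``sampling_rate`` is required; filtering runs along axis 0).
    The two passes double the effective order and cancel the phase response.
    """
    if isinstance(series, MarkerFrameSeries):
        filtered = lowpass_zero_phase(
            series.positions, cutoff_hz, order, series.sampling_rate
        )
        return replace(series, positions=filtered)
    if isinstance(series, AngleSeries):
        filtered = lowpass_zero_phase(
            series.values, cutoff_hz, order, series.sampling_rate
        )
        return AngleSeries(np.maximum(filtered, 0.0), series.sampling_rate)
    if sampling_rate is None:
        raise ValueError("sampling_rate required for plain arrays")
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=0)


def compute_joint_centers(
    series: MarkerFrameSeries, neck_projection_fraction: float = 0.0
) -> JointCenters:
    """Estimate joint centers from marker geometry, per frame.

    Conventions (a single swappable strategy; see the methods note):

    * neck: midpoint of the two ear markers, optionally projected toward C7 by
      ``neck_projection_fraction`` (default 0, i.e. the ear midpoint itself,
      which is a fixed point of pure head rotation);
    * shoulder: midpoint of the two acromion markers;
    * thoracolumbar: midpoint of T8 and T12.
    """
    if not 0.0 <= neck_projection_fraction < 1.0:
        raise ValueError("neck_projection_fraction must lie in [0, 1)")
    ear_mid = 0.5 * (series.marker("ear_L") + series.marker("ear_R"))
    neck = ear_mid + neck_projection_fraction * (series.marker("C7") - ear_mid)
    shoulder = 0.5 * (series.marker("acromion_L") + series.marker("acromion_R"))
    thoraco = 0.5 * (series.marker("T8") + series.marker("T12"))
    return JointCenters(neck=neck, shoulder=shoulder, thoracolumbar=thoraco)


def _orthonormal_frame(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Stack per-frame rotation matrices with columns (x, y, z).

    ``primary`` becomes the x axis (lateral), ``secondary`` is orthogonalized
    against it to form the z axis (longitudinal); y completes the right-handed
    triad (anterior).
    """
    x = primary / _norm_checked(primary)
    z = secondary - np.sum(secondary * x, axis=1, keepdims=True) * x
    z = z / _norm_checked(z)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)


def _norm_checked(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("degenerate (zero-length) segment vector")
    return n


def neck_angles(centers: JointCenters, series: MarkerFrameSeries) -> np.ndarray:
    """Three-dimensional neck joint angles, degrees, shape ``(n_frames, 3)``.

    The head segment frame is built from the ear line (lateral axis) and the
    ear-midpoint-to-head-top vector (longitudinal axis); the torso frame from
    the acromion line and the thoracolumbar-to-neck axis.  The relative
    rotation is decomposed as intrinsic rotations about the torso-fixed axes
    in the order flexion/extension (lateral axis), lateral bending (anterior
    axis), axial rotation (longitudinal axis).  The decomposition order is a
    convention; the downstream magnitude is insensitive to it for the small
    angles typical of seated listening.
    """
    ear_l, ear_r = series.marker("ear_L"), series.marker("ear_R")
    ear_mid = 0.5 * (ear_l + ear_r)
    head_frames = _orthonormal_frame(ear_r - ear_l, series.marker("head_top") - ear_mid)
    torso_frames = _orthonormal_frame(
        series.marker("acromion_R") - series.marker("acromion_L"),
        centers.neck - centers.thoracolumbar,
    )
    rel = np.einsum("nij,njk->nik", torso_frames.transpose(0, 2, 1), head_frames)
    return Rotation.from_matrix(rel).as_euler("XYZ", degrees=True)


def angle_norm(angles3d: np.ndarray, sampling_rate: float) -> AngleSeries:
    """Euclidean norm of the three angle components: the 1-D movement signal."""
    angles3d = np.asarray(angles3d, dtype=float)
    if not np.all(np.isfinite(angles3d)):
        raise ValueError("angle components must be finite")
    return AngleSeries(np.linalg.norm(angles3d, axis=-1), sampling_rate)


def markers_to_angle(
    series: MarkerFrameSeries,
    trigger_sample: int = 0,
    duration_s: float | None = None,
    cutoff_hz: float = 5.0,
    filter_order: int = 4,
    max_gap: int = 10,
    neck_projection_fraction: float = 0.0,
) -> AngleSeries:
    """Full chain: gaps -> trim -> low-pass -> joint centers -> angles -> norm."""
    if duration_s is None:
        duration_s = (series.n_frames - trigger_sample) / series.sampling_rate
    series = fill_gaps(series, max_gap=max_gap)
    series = trim_to_stimulus(series, trigger_sample, duration_s)
    series = lowpass_zero_phase(series, cutoff_hz, filter_order)
    centers = compute_joint_centers(series, neck_projection_fraction)
    return angle_norm(neck_angles(centers, series), series.sampling_rate)
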