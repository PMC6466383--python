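"""Raw triaxial acceleration -> per-epoch synthetic-acceleration features.

Replicates the signal chain of a waist-worn triaxial accelerometer used for
activity calibration in young children: the device samples the vertical (x),
anteroposterior (y) and mediolateral (z) axes at a nominal 32 Hz, removes the
gravitational component with a 0.7 Hz high-pass filter, reduces each axis to
the time-normalised integral of the rectified signal per epoch, and combines
the three per-axis amplitudes into a "synthetic acceleration" (the Euclidean
vector magnitude, in mG).

Two per-epoch channels are produced:

* ``filtered_synthetic_mg`` — vector magnitude of the high-pass-filtered axes,
  i.e. movement acceleration with gravity excluded;
* ``unfiltered_synthetic_mg`` — vector magnitude of the per-epoch mean-removed
  but otherwise unfiltered axes, so slow postural movement is retained while
  the static ~1000 mG gravity offset is not.

Their ratio (unfiltered / filtered) is the discriminant used downstream to
separate ambulatory from non-ambulatory activity: locomotion concentrates its
energy well above the 0.7 Hz cutoff, so both channels nearly coincide and the
ratio sits near 1; household/sedentary play contains slow components that
survive only in the unfiltered channel, inflating the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _sps

__all__ = [
    "FilterSpec",
    "RawTriaxialRecording",
    "EpochFeatures",
    "high_pass_filter",
    "epoch_rectified_amplitude",
    "synthetic_acceleration",
    "compute_epoch_features",
]

#: Sensor resolution of the device, in mG; default floor below which the
#: filtered channel is considered indistinguishable from a motionless device.
DEVICE_RESOLUTION_MG = 3.0


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter used to strip the gravitational component.

    Parameters
    ----------
    cutoff_hz : float
        -3 dB cutoff frequency. Default 0.7 Hz, the device's published value.
    order : int
        Butterworth order (of the underlying analog prototype). Default 2.
    zero_phase : bool
        Apply the filter forward and backward (``filtfilt``), doubling the
        effective attenuation but removing phase distortion so epoch
        boundaries are not smeared. Default True.
    """

    cutoff_hz: float = 0.7
    order: int = 2
    zero_phase: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not 0.0 < self.cutoff_hz < sampling_rate_hz / 2.0:
            raise ValueError(
                f"cutoff_hz must lie in (0, Nyquist={sampling_rate_hz / 2.0} Hz), "
                f"got {self.cutoff_hz}"
            )

    def sos(self, sampling_rate_hz: float) -> np.ndarray:
        """Second-order-sections representation at the given sampling rate."""
        self.validate(sampling_rate_hz)
        return _sps.butter(
            self.order, self.cutoff_hz, btype="highpass", fs=sampling_rate_hz,
            output="sos",
        )

    def frequency_response(
        self, freqs_hz: np.ndarray, sampling_rate_hz: float
    ) -> np.ndarray:
        """Magnitude response at ``freqs_hz`` of the filter as applied.

        Forward-backward application squares the single-pass magnitude.
        """
        sos = self.sos(sampling_rate_hz)
        _, h = _sps.sosfreqz(sos, worN=np.atleast_1d(freqs_hz), fs=sampling_rate_hz)
        mag = np.abs(h)
        return mag**2 if self.zero_phase else mag


@dataclass
class RawTriaxialRecording:
    """Sampled x/y/z acceleration in mG with its sampling rate.

    Axes follow the device convention: x vertical, y anteroposterior,
    z mediolateral.
    """

    samples_x: np.ndarray
    samples_y: np.ndarray
    samples_z: np.ndarray
    sampling_rate_hz: float = 32.0
    start_time: Optional[float] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples_x = np.asarray(self.samples_x, dtype=float)
        self.samples_y = np.asarray(self.samples_y, dtype=float)
        self.samples_z = np.asarray(self.samples_z, dtype=float)
        n = len(self.samples_x)
        if len(self.samples_y) != n or len(self.samples_z) != n:
            raise ValueError(
                "all three axes must have equal length; got "
                f"x={n}, y={len(self.samples_y)}, z={len(self.samples_z)}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")

    @property
    def n_samples(self) -> int:
        return len(self.samples_x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.samples_x, self.samples_y, self.samples_z


@dataclass
class EpochFeatures:
    """Per-epoch reduction of a recording.

    ``ratio`` is ``unfiltered_synthetic_mg / filtered_synthetic_mg`` and is
    ``None`` whenever the filtered channel falls below the configured floor
    (a motionless device); such epochs are flagged "still" downstream.
    """

    epoch_index: int
    epoch_length_s: float
    filtered_synthetic_mg: float
    unfiltered_synthetic_mg: float
    ratio: Optional[float] = None
    activity_label: Optional[str] = None
    measured_met: Optional[float] = None

    def __post_init__(self) -> None:
        if self.filtered_synthetic_mg < 0 or self.unfiltered_synthetic_mg < 0:
            raise ValueError("synthetic accelerations must be non-negative")
        if self.ratio is not None and self.ratio <= 0:
            raise ValueError(f"ratio, when set, must be > 0; got {self.ratio}")


def high_pass_filter(
    series: Sequence[float], sampling_rate_hz: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """High-pass filter one acceleration axis, removing the DC/gravity component.

    Returns a series of the same length. With ``spec.zero_phase`` the filter
    runs forward and backward (no phase lag, squared magnitude response);
    otherwise a single causal pass is used.
    """
    x = np.asarray(series, dtype=float)
    sos = spec.sos(sampling_rate_hz)
    min_len = 3 * (2 * spec.order)  # conservative warm-up for filtfilt padding
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} is shorter than the filter warm-up "
            f"requirement ({min_len} samples for order {spec.order})"
        )
    if spec.zero_phase:
        return _sps.sosfiltfilt(sos, x)
    return _sps.sosfilt(sos, x)


def epoch_rectified_amplitude(
    series: Sequence[float], sampling_rate_hz: float, epoch_length_s: float
) -> np.ndarray:
    """Mean rectified amplitude of one axis per complete epoch, in mG.

    The device computes the integral of the absolute acceleration over each
    epoch; normalising by epoch duration keeps the result in mG. A trailing
    partial epoch is dropped rather than padded.
    """
    if epoch_length_s <= 0:
        raise ValueError(f"epoch_length_s must be > 0, got {epoch_length_s}")
    samples_per_epoch = int(round(epoch_length_s * sampling_rate_hz))
    if samples_per_epoch < 1:
        raise ValueError(
            f"epoch of {epoch_length_s} s holds no samples at {sampling_rate_hz} Hz"
        )
    x = np.asarray(series, dtype=float)
    n_epochs = x.size // samples_per_epoch
    if n_epochs == 0:
        return np.empty(0)
    trimmed = x[: n_epochs * samples_per_epoch]
    return np.abs(trimmed).reshape(n_epochs, samples_per_epoch).mean(axis=1)


def synthetic_acceleration(amp_x: float, amp_y: float, amp_z: float) -> float:
    """Vector magnitude sqrt(x^2 + y^2 + z^2) of three per-axis amplitudes (mG)."""
    a = np.asarray([amp_x, amp_y, amp_z], dtype=float)
    if np.any(a < 0):
        raise ValueError(f"per-axis amplitudes must be non-negative, got {a.tolist()}")
    return float(np.sqrt(np.sum(a**2)))


def _epoch_means_removed(x: np.ndarray, samples_per_epoch: int, n_epochs: int) -> np.ndarray:
    seg = x[: n_epochs * samples_per_epoch].reshape(n_epochs, samples_per_epoch)
    return seg - seg.mean(axis=1, keepdims=True)


def compute_epoch_features(
    recording: RawTriaxialRecording,
    spec: FilterSpec = FilterSpec(),
    epoch_length_s: float = 60.0,
    ratio_floor_mg: float = DEVICE_RESOLUTION_MG,
) -> list[EpochFeatures]:
    """Full per-epoch feature extraction for one recording.

    Per epoch: the filtered synthetic acceleration comes from the high-pass
    filtered axes; the unfiltered synthetic acceleration from per-epoch
    mean-removed (but not high-pass filtered) axes, so static gravity is
    excluded from both channels while slow postural movement survives only in
    the unfiltered one. The ratio is set only where the filtered channel is at
    least ``ratio_floor_mg`` (default: the 3 mG sensor resolution).
    """
    spec.validate(recording.sampling_rate_hz)
    samples_per_epoch = int(round(epoch_length_s * recording.sampling_rate_hz))
    n_epochs = recording.n_samples // samples_per_epoch if samples_per_epoch else 0
    if samples_per_epoch < 1 or n_epochs < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples "
            f"({recording.duration_s:.1f} s) is shorter than one epoch; "
            f"at least {samples_per_epoch} samples ({epoch_length_s} s at "
            f"{recording.sampling_rate_hz} Hz) are required"
        )

    filtered_amps = []
    unfiltered_amps = []
    for axis in recording.axes():
        hp = high_pass_filter(axis, recording.sampling_rate_hz, spec)
        filtered_amps.append(
            epoch_rectified_amplitude(hp, recording.sampling_rate_hz, epoch_length_s)
        )
        detrended = _epoch_means_removed(axis, samples_per_epoch, n_epochs)
        unfiltered_amps.append(np.abs(detrended).mean(axis=1))
    filtered_amps = np.stack(filtered_amps)  # (3, n_epochs)
    unfiltered_amps = np.stack(unfiltered_amps)

    filtered_syn = np.sqrt((filtered_amps**2).sum(axis=0))
    unfiltered_syn = np.sqrt((unfiltered_amps**2).sum(axis=0))

    out: list[EpochFeatures] = []
    for i in range(n_epochs):
        f, u = float(filtered_syn[i]), float(unfiltered_syn[i])
        ratio = u / f if f >= ratio_floor_mg else None
        out.append(
            EpochFeatures(
                epoch_index=i,
                epoch_length_s=epoch_length_s,
                filtered_synthetic_mg=f,
                unfiltered_synthetic_mg=u,
                ratio=ratio,
            )
        )
    return out
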