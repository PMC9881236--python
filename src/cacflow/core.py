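"""Acquisition parameters, shared domain containers, and unit conversions.

Conventions used throughout the package:

* velocities are in cm/s, frequencies in Hz, grid coordinates in mm;
* clutter filter cutoffs are dimensionless fractions of the PRF;
* positive axial velocity means motion toward the transducer;
* channel data are complex baseband (IQ) samples indexed
  ``(axial, lateral, channel, slow_time, frame)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class InvalidArgumentError(ValueError):
    """Raised when an operation receives an argument outside its domain."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Color flow acquisition metadata.

    Parameters
    ----------
    f0 : float
        Transmit center frequency in Hz.
    prf : float
        Pulse repetition frequency (slow-time sampling rate) in Hz.
    n_channels : int
        Number of receive channels M.
    ensemble : int
        Slow-time ensemble size K (firings per imaging location per frame).
    c : float
        Sound speed in m/s.  Defaults to the soft-tissue convention 1540.
    frame_rate : float
        Color flow frame rate in Hz.
    n_frames : int
        Number of consecutively acquired frames.
    """

    f0: float
    prf: float
    n_channels: int
    ensemble: int
    c: float = 1540.0
    frame_rate: float = 12.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        for name in ("f0", "prf", "c", "frame_rate"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be strictly positive")
        if self.n_channels < 2:
            raise InvalidArgumentError("n_channels must be >= 2")
        if self.ensemble < 2:
            raise InvalidArgumentError("ensemble must be >= 2")
        if self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")

    def to_dict(self) -> dict:
        return {
            "f0": float(self.f0),
            "prf": float(self.prf),
            "n_channels": int(self.n_channels),
            "ensemble": int(self.ensemble),
            "c": float(self.c),
            "frame_rate": float(self.frame_rate),
            "n_frames": int(self.n_frames),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)


def default_acquisition(n_frames: int = 20) -> AcquisitionParams:
    """Reference acquisition: 3.5 MHz curvilinear abdominal color flow,
    3 kHz PRF, 64 receive channels, K=14 ensembles, frames at 12 Hz."""
    return AcquisitionParams(
        f0=3.5e6, prf=3e3, n_channels=64, ensemble=14,
        c=1540.0, frame_rate=12.0, n_frames=n_frames,
    )


@dataclass(frozen=True)
class PixelGrid:
    """Rectangular axial x lateral pixel grid, pixel-center positions in mm."""

    axial_mm: np.ndarray
    lateral_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "axial_mm", np.asarray(self.axial_mm, float))
        object.__setattr__(self, "lateral_mm", np.asarray(self.lateral_mm, float))
        if self.axial_mm.ndim != 1 or self.lateral_mm.ndim != 1:
            raise InvalidArgumentError("grid axes must be 1-D")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.axial_mm.size, self.lateral_mm.size)

    @property
    def spacing_mm(self) -> tuple[float, float]:
        def _sp(ax: np.ndarray) -> float:
            return float(ax[1] - ax[0]) if ax.size > 1 else 1.0
        return (_sp(self.axial_mm), _sp(self.lateral_mm))

    @classmethod
    def regular(cls, shape: tuple[int, int], spacing_mm: float,
                origin_mm: tuple[float, float] = (0.0, 0.0)) -> "PixelGrid":
        n_ax, n_lat = shape
        return cls(
            axial_mm=origin_mm[0] + spacing_mm * np.arange(n_ax),
            lateral_mm=origin_mm[1] + spacing_mm * np.arange(n_lat),
        )


@dataclass
class ChannelEnsemble:
    """Focused (time-delayed) complex IQ receive channel data.

    ``data`` has shape ``(n_axial, n_lateral, M, K, n_frames)``.
    """

    data: np.ndarray
    grid: PixelGrid
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 4:  # single frame convenience
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 5:
            raise InvalidArgumentError(
                "channel data must be (axial, lateral, channel, slow_time, frame)")
        n_ax, n_lat, m, k, _ = self.data.shape
        if (n_ax, n_lat) != self.grid.shape:
            raise InvalidArgumentError("data grid shape does not match grid")
        if m != self.acq.n_channels:
            raise InvalidArgumentError("channel dimension does not match acq.n_channels")
        if k != self.acq.ensemble:
            raise InvalidArgumentError("slow-time dimension does not match acq.ensemble")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("channel data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass
class BeamEnsemble:
    """Beamsummed complex IQ data, shape ``(n_axial, n_lateral, K, n_frames)``."""

    data: np.ndarray
    grid: PixelGrid
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise InvalidArgumentError(
                "beam data must be (axial, lateral, slow_time, frame)")
        if self.data.shape[2] != self.acq.ensemble:
            raise InvalidArgumentError("slow-time dimension does not match acq.ensemble")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("beam data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class ROI:
    """Region of interest: a rectangle in grid mm coordinates or an explicit
    pixel mask.  Exactly one of the two must be given."""

    axial_mm: tuple[float, float] | None = None
    lateral_mm: tuple[float, float] | None = None
    mask: np.ndarray | None = field(default=None)

    def mask_for(self, grid: PixelGrid) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, bool)
            if m.shape != grid.shape:
                raise InvalidArgumentError("ROI mask shape does not match grid")
        else:
            if self.axial_mm is None or self.lateral_mm is None:
                raise InvalidArgumentError("ROI needs a rectangle or a mask")
            a0, a1 = self.axial_mm
            l0, l1 = self.lateral_mm
            in_ax = (grid.axial_mm >= a0) & (grid.axial_mm <= a1)
            in_lat = (grid.lateral_mm >= l0) & (grid.lateral_mm <= l1)
            m = in_ax[:, None] & in_lat[None, :]
        if not m.any():
            raise InvalidArgumentError("ROI selects no pixels on this grid")
        return m


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def cutoff_to_velocity(cutoff_fraction: float, acq: AcquisitionParams) -> float:
    """Velocity cutoff (cm/s) of a clutter filter expressed as a PRF fraction.

    ``v_c = c * (f_c * PRF) / (2 * f0)``, i.e. the axial velocity whose
    Doppler shift equals the cutoff frequency.
    """
    if not 0 <= cutoff_fraction < 0.5:
        raise InvalidArgumentError("cutoff_fraction must lie in [0, 0.5)")
    return 100.0 * acq.c * (cutoff_fraction * acq.prf) / (2.0 * acq.f0)


def nyquist_velocity(acq: AcquisitionParams) -> float:
    """Aliasing-free axial velocity limit, cm/s: ``c * PRF / (4 * f0)``."""
    return 100.0 * acq.c * acq.prf / (4.0 * acq.f0)


def doppler_shift(v_axial_cm_s: float, acq: AcquisitionParams) -> float:
    """Doppler frequency (Hz) of an axial velocity: ``2 * f0 * v / c``.

    Emits a warning when ``|v|`` exceeds the Nyquist velocity (the returned
    shift would alias at the PRF).
    """
    v = np.asarray(v_axial_cm_s, float)
    if np.any(np.abs(v) > nyquist_velocity(acq) * (1 + 1e-12)):
        warnings.warn("axial velocity beyond Nyquist limit: Doppler shift aliases",
                      RuntimeWarning, stacklevel=2)
    out = 2.0 * acq.f0 * (v / 100.0) / acq.c
    return float(out) if np.isscalar(v_axial_cm_s) else out


def velocity_to_slow_time_fraction(v_axial_cm_s: float, acq: AcquisitionParams) -> float:
    """Slow-time frequency fraction whose phase ramp the velocity estimator
    maps back to ``v_axial_cm_s``.

    The estimator's sign convention (positive velocity toward the transducer,
    with a leading minus in the phase-to-velocity map) puts motion toward the
    transducer at negative slow-time frequency, hence the negation.
    """
    return -doppler_shift(v_axial_cm_s, acq) / acq.prf


def mean_axial_velocity_from_flow(volume_rate_ml_min: float,
                                  vessel_diameter_mm: float,
                                  doppler_angle_deg: float) -> float:
    """Mean axial (beam-projected) velocity, cm/s, of volumetric flow through
    a cylindrical vessel at a Doppler angle: ``(Q / A) * cos(angle)``."""
    if volume_rate_ml_min <= 0:
        raise InvalidArgumentError("volume rate must be positive")
    if vessel_diameter_mm <= 0:
        raise InvalidArgumentError("vessel diameter must be positive")
    if not 0 <= doppler_angle_deg <= 90:
        raise InvalidArgumentError("Doppler angle must lie in [0, 90] degrees")
    q_cm3_s = volume_rate_ml_min / 60.0
    area_cm2 = np.pi * (vessel_diameter_mm / 20.0) ** 2
    return q_cm3_s / area_cm2 * np.cos(np.deg2rad(doppler_angle_deg))
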