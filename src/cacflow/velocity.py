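"""Beamsum and 2-D autocorrelation (Kasai) velocity estimation.

The mean slow-time phase shift of the beamsummed IQ signal U is the
four-quadrant angle of the lag-one autocorrelation accumulated over the
ensemble and an optional spatial kernel:

    phi = angle( sum_{k=1..K-1} sum_{r in kernel} U[r, k+1] conj(U[r, k]) )

and converts to axial velocity via  v = -c PRF phi / (4 pi f0),  positive
toward the transducer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (AcquisitionParams, BeamEnsemble, ChannelEnsemble,
                   InvalidArgumentError, PixelGrid)

__all__ = ["VelocityMap", "beamsum", "kasai_phase", "phase_to_velocity",
           "velocity_map", "kernel_size_pixels"]


@dataclass
class VelocityMap:
    """Per-pixel axial velocity estimates.

    ``v_hat`` (cm/s) and ``phi_hat`` (radians) have shape
    ``(n_axial, n_lateral, n_frames)``.  ``no_signal`` flags pixels whose
    autocorrelation accumulator was exactly zero (no detectable energy);
    ``rejected`` is set by priority encoding / coherence thresholding.
    """

    v_hat: np.ndarray
    phi_hat: np.ndarray
    grid: PixelGrid
    acq: AcquisitionParams
    no_signal: np.ndarray | None = None
    rejected: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.v_hat = np.asarray(self.v_hat, float)
        self.phi_hat = np.asarray(self.phi_hat, float)
        if self.v_hat.ndim == 2:
            self.v_hat = self.v_hat[..., np.newaxis]
            self.phi_hat = self.phi_hat[..., np.newaxis]
        if np.any(np.abs(self.phi_hat) > np.pi + 1e-9):
            raise InvalidArgumentError("|phi_hat| must not exceed pi")

    @property
    def n_frames(self) -> int:
        return self.v_hat.shape[-1]

    def copy(self) -> "VelocityMap":
        return VelocityMap(
            v_hat=self.v_hat.copy(), phi_hat=self.phi_hat.copy(),
            grid=self.grid, acq=self.acq,
            no_signal=None if self.no_signal is None else self.no_signal.copy(),
            rejected=None if self.rejected is None else self.rejected.copy())


def beamsum(dataset: ChannelEnsemble) -> BeamEnsemble:
    """Coherent sum across the channel dimension (delay-and-sum output)."""
    return BeamEnsemble(data=dataset.data.sum(axis=2),
                        grid=dataset.grid, acq=dataset.acq)


def _lag_one_accumulator(beams: BeamEnsemble) -> np.ndarray:
    u = beams.data  # (ax, lat, K, frame)
    return np.sum(u[:, :, 1:, :] * np.conj(u[:, :, :-1, :]), axis=2)


def kernel_size_pixels(kernel_mm: tuple[float, float] | float | None,
                       grid: PixelGrid) -> tuple[int, int]:
    """Odd pixel counts covering a kernel extent given in mm (1x1 pixel when
    ``kernel_mm`` is None)."""
    if kernel_mm is None:
        return (1, 1)
    if np.isscalar(kernel_mm):
        kernel_mm = (float(kernel_mm), float(kernel_mm))
    d_ax, d_lat = grid.spacing_mm
    size = []
    for extent, d in zip(kernel_mm, (d_ax, d_lat)):
        if extent <= 0:
            raise InvalidArgumentError("kernel extent must be positive")
        n = max(int(round(extent / d)), 1)
        size.append(n if n % 2 == 1 else n + 1)
    return tuple(size)


def _kernel_sum(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Sum of x over a truncated (border-clipped) rectangular kernel, applied
    to the two leading grid axes of an (ax, lat, frame) array."""
    if size == (1, 1):
        return x
    full = (size[0], size[1]) + (1,) * (x.ndim - 2)
    scale = size[0] * size[1]
    if np.iscomplexobj(x):
        return (ndimage.uniform_filter(x.real, full, mode="constant") +
                1j * ndimage.uniform_filter(x.imag, full, mode="constant")) * scale
    return ndimage.uniform_filter(x, full, mode="constant") * scale


def kasai_phase(beams: BeamEnsemble, pixel: tuple[int, int],
                kernel_mm: tuple[float, float] | float | None = None,
                frame: int = 0) -> float:
    """Mean phase shift (radians, in (-pi, pi]) at one pixel.

    Returns 0 (flagged via :func:`velocity_map`) when the accumulator is
    exactly zero — no detectable motion or energy.
    """
    if beams.acq.ensemble < 2:
        raise InvalidArgumentError("need K >= 2 slow-time samples")
    acc = _lag_one_accumulator(beams)
    acc = _kernel_sum(acc, kernel_size_pixels(kernel_mm, beams.grid))
    val = acc[pixel[0], pixel[1], frame]
    return float(np.angle(val)) if val != 0 else 0.0


def phase_to_velocity(phi: np.ndarray | float, acq: AcquisitionParams) -> np.ndarray | float:
    """Axial velocity, cm/s: ``v = -c PRF phi / (4 pi f0)``."""
    phi_arr = np.asarray(phi, float)
    if np.any(np.abs(phi_arr) > np.pi + 1e-9):
        raise InvalidArgumentError("|phi| must not exceed pi")
    v = -100.0 * acq.c * acq.prf * phi_arr / (4.0 * np.pi * acq.f0)
    return float(v) if np.isscalar(phi) else v


def velocity_map(beams: BeamEnsemble,
                 kernel_mm: tuple[float, float] | float | None = None,
                 acq: AcquisitionParams | None = None) -> VelocityMap:
    """Per-pixel Kasai phase + velocity over all frames."""
    acq = acq or beams.acq
    acc = _lag_one_accumulator(beams)
    acc = _kernel_sum(acc, kernel_size_pixels(kernel_mm, beams.grid))
    no_signal = acc == 0
    phi = np.where(no_signal, 0.0, np.angle(acc))
    return VelocityMap(v_hat=phase_to_velocity(phi, acq), phi_hat=phi,
                       grid=beams.grid, acq=acq, no_signal=no_signal)
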