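"""Receive-aperture spatial coherence: lag profiles, short-lag sums, LOC.

The normalized correlation between channel signals at element separation
(lag) m, averaged over element pairs and slow-time samples, is

    R[m] = 1/(K(M-m)) sum_k sum_i  u_i[k] conj(u_{i+m}[k]) / (|u_i[k]| |u_{i+m}[k]|)

Each per-sample term has unit modulus, so |R[m]| <= 1.  The short-lag
spatial coherence (SLSC) sums the real parts of the first Q lags; for
diffuse speckle and a rectangular receive aperture the underlying channel
correlation follows the van Cittert-Zernike triangle 1 - m/M.

Because of the per-sample magnitude normalization, the expected value of
R[m] for jointly circular Gaussian channels with correlation coefficient
rho is (pi/4) rho 2F1(1/2, 1/2; 2; rho^2), slightly below rho; see
:func:`cacflow.synthetic.expected_measured_coherence`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ChannelEnsemble, InvalidArgumentError, ROI

__all__ = [
    "CoherenceProfile", "SLSCStack", "correlation_profile", "slsc_value",
    "theoretical_max_slsc", "slsc_stack", "lag_one_coherence_roi",
    "normalized_lag_correlations",
]


@dataclass
class CoherenceProfile:
    """Per-lag normalized channel correlation, lags m = 1..len(r_hat)."""

    r_hat: np.ndarray  # complex, index 0 holds lag m=1
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.r_hat = np.asarray(self.r_hat, complex)
        if np.any(np.abs(self.r_hat) > 1 + 1e-9):
            raise InvalidArgumentError("|R[m]| must not exceed 1")


@dataclass
class SLSCStack:
    """Per-pixel, per-filter SLSC values.

    ``values`` has shape ``(n_filters, n_axial, n_lateral, n_frames)``;
    ``cutoff_fractions`` labels the filter axis.
    """

    values: np.ndarray
    q: int
    cutoff_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 4:
            raise InvalidArgumentError("stack must be (filter, axial, lateral, frame)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("SLSC values must be finite")
        if np.any(np.abs(self.values) > self.q + 1e-9):
            raise InvalidArgumentError("SLSC values must lie within [-Q, Q]")


def normalized_lag_correlations(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Vectorized Eq-style lag correlations.

    Parameters
    ----------
    data : complex array, shape ``(..., M, K)``
        Channel x slow-time samples, any leading pixel/frame axes.
    max_lag : int
        Highest lag to compute (1 <= max_lag <= M-1).

    Returns
    -------
    complex array, shape ``(..., max_lag)``: ``R[m]`` for m = 1..max_lag.
    Zero-magnitude samples are excluded pairwise with the divisor reduced;
    a lag with no valid pairs yields 0.
    """
    data = np.asarray(data)
    m_tot = data.shape[-2]
    if m_tot < 2:
        raise InvalidArgumentError("need at least two channels")
    if not 1 <= max_lag <= m_tot - 1:
        raise InvalidArgumentError("max_lag out of range")
    mag = np.abs(data)
    valid = mag > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        phasor = np.where(valid, data / np.where(valid, mag, 1.0), 0.0)
    out = np.empty(data.shape[:-2] + (max_lag,), dtype=complex)
    for m in range(1, max_lag + 1):
        prod = phasor[..., : m_tot - m, :] * np.conj(phasor[..., m:, :])
        count = np.sum(valid[..., : m_tot - m, :] & valid[..., m:, :], axis=(-2, -1))
        s = np.sum(prod, axis=(-2, -1))
        out[..., m - 1] = np.where(count > 0, s / np.maximum(count, 1), 0.0)
    return out


def correlation_profile(pixel_data: np.ndarray, max_lag: int | None = None) -> CoherenceProfile:
    """Coherence profile of a single pixel's ``(M, K)`` channel ensemble."""
    pixel_data = np.asarray(pixel_data)
    if pixel_data.ndim != 2:
        raise InvalidArgumentError("pixel data must be (channel, slow_time)")
    m_tot = pixel_data.shape[0]
    if max_lag is None:
        max_lag = m_tot - 1
    r = normalized_lag_correlations(pixel_data, max_lag)
    return CoherenceProfile(r_hat=r, all_zero=bool(np.all(pixel_data == 0)))


def slsc_value(profile: CoherenceProfile, q: int) -> float:
    """Short-lag spatial coherence: sum of Re R[m] for m = 1..q."""
    if not 1 <= q <= profile.r_hat.size:
        raise InvalidArgumentError("q out of range for this profile")
    return float(np.sum(profile.r_hat[:q].real))


def theoretical_max_slsc(m_channels: int, q: int) -> float:
    """SLSC of ideal speckle under a rectangular aperture (triangle
    coherence ``1 - m/M``): ``q - q(q+1)/(2M)``."""
    if not 1 <= q <= m_channels - 1:
        raise InvalidArgumentError("q must lie in [1, M-1]")
    return q - q * (q + 1) / (2.0 * m_channels)


def slsc_stack(filtered_datasets: list[ChannelEnsemble], q: int,
               cutoff_fractions: np.ndarray | None = None) -> SLSCStack:
    """Per-pixel SLSC at the output of each filter in a bank.

    All datasets must share the same grid and acquisition.  Layer order
    follows the input list (bank order).
    """
    if not filtered_datasets:
        raise InvalidArgumentError("need at least one dataset")
    ref = filtered_datasets[0]
    for ds in filtered_datasets[1:]:
        if ds.grid.shape != ref.grid.shape or ds.acq != ref.acq:
            raise InvalidArgumentError("datasets must share grid and acquisition")
    if not 1 <= q <= ref.acq.n_channels - 1:
        raise InvalidArgumentError("q must lie in [1, M-1]")
    layers = []
    for ds in filtered_datasets:
        # (ax, lat, M, K, frame) -> (ax, lat, frame, M, K)
        d = np.moveaxis(ds.data, 4, 2)
        r = normalized_lag_correlations(d, q)
        layers.append(np.sum(r.real, axis=-1))
    if cutoff_fractions is None:
        cutoff_fractions = np.full(len(layers), np.nan)
    return SLSCStack(values=np.stack(layers), q=q,
                     cutoff_fractions=np.asarray(cutoff_fractions, float))


def lag_one_coherence_roi(dataset: ChannelEnsemble, roi: ROI) -> float:
    """ROI-mean lag-one coherence (LOC): mean over ROI pixels and frames of
    Re R[1].  A scalar clutter/noise level metric."""
    mask = roi.mask_for(dataset.grid)
    d = np.moveaxis(dataset.data[mask], 3, 1)  # (npx, frame, M, K)
    r1 = normalized_lag_correlations(d, 1)[..., 0]
    return float(np.mean(r1.real))
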