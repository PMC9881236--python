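"""Slow-time high-pass clutter filter bank with projection initialization.

Clutter (wall) filters run along the slow-time axis of each receive channel.
On the short ensembles typical of color flow (K ~ 14), a plainly-initialized
IIR recursion rings for a large part of the ensemble, so every IIR member is
*projection initialized*: the component of the input lying in a low-order
polynomial (default: constant/DC) slow-time subspace is removed before the
recursion runs from rest.  A constant complex input of any value therefore
produces identically zero output — the defining contract of the technique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ChannelEnsemble, InvalidArgumentError

__all__ = [
    "ClutterFilter", "ClutterFilterBank", "design_highpass",
    "identity_filter", "default_bank", "filter_slow_time", "apply_bank",
]


@dataclass(frozen=True)
class ClutterFilter:
    """A single slow-time filter: an IIR high-pass or the identity member.

    ``cutoff_fraction`` is the half-power frequency as a fraction of the PRF;
    0 encodes the "no filter" identity member.
    """

    cutoff_fraction: float
    order: int
    b: np.ndarray
    a: np.ndarray
    kind: str  # "iir_highpass" | "identity"
    projection_order: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff_fraction < 0.5:
            raise InvalidArgumentError("cutoff_fraction must lie in [0, 0.5)")
        if self.kind not in ("iir_highpass", "identity"):
            raise InvalidArgumentError(f"unknown filter kind {self.kind!r}")
        if self.kind == "identity" and self.cutoff_fraction != 0:
            raise InvalidArgumentError("identity member must have cutoff 0")

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity"

    def response(self, frequency_fraction: np.ndarray) -> np.ndarray:
        """Complex frequency response H at slow-time frequencies given as
        fractions of the PRF (Nyquist = 0.5)."""
        w = 2 * np.pi * np.atleast_1d(np.asarray(frequency_fraction, float))
        if self.is_identity:
            return np.ones_like(w, dtype=complex)
        _, h = signal.freqz(self.b, self.a, worN=w)
        return h


def identity_filter() -> ClutterFilter:
    """The "no filter" bank member: output equals input bit-exactly."""
    return ClutterFilter(cutoff_fraction=0.0, order=0,
                         b=np.array([1.0]), a=np.array([1.0]), kind="identity")


def design_highpass(cutoff_fraction: float, order: int = 2,
                    projection_order: int = 0) -> ClutterFilter:
    """Butterworth high-pass in the slow-time domain.

    The half-power (|H|^2 = 1/2) frequency sits at ``cutoff_fraction * PRF``
    and |H(DC)| = 0.
    """
    if not 0 < cutoff_fraction < 0.5:
        raise InvalidArgumentError("cutoff_fraction must lie in (0, 0.5)")
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    if projection_order < 0:
        raise InvalidArgumentError("projection_order must be >= 0")
    # scipy normalizes Wn to the Nyquist frequency (0.5 of the sampling rate)
    b, a = signal.butter(order, 2.0 * cutoff_fraction, btype="highpass")
    return ClutterFilter(cutoff_fraction=float(cutoff_fraction), order=int(order),
                         b=b, a=a, kind="iir_highpass",
                         projection_order=int(projection_order))


@dataclass(frozen=True)
class ClutterFilterBank:
    """Ordered clutter filter bank: strictly ascending cutoffs, with at most
    one identity ("no filter") member, which must come first."""

    filters: tuple[ClutterFilter, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(self.filters))
        if not self.filters:
            raise InvalidArgumentError("bank must contain at least one filter")
        cut = [f.cutoff_fraction for f in self.filters]
        if any(c2 <= c1 for c1, c2 in zip(cut, cut[1:])):
            raise InvalidArgumentError("bank cutoffs must be strictly increasing")
        if any(f.is_identity for f in self.filters[1:]):
            raise InvalidArgumentError("identity member must be first and unique")

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)

    def __getitem__(self, i: int) -> ClutterFilter:
        return self.filters[i]

    @property
    def cutoff_fractions(self) -> np.ndarray:
        return np.array([f.cutoff_fraction for f in self.filters])


def default_bank(order: int = 2, low: float = 0.03, high: float = 0.24,
                 n_highpass: int = 8, include_identity: bool = True,
                 projection_order: int = 0) -> ClutterFilterBank:
    """The evaluation bank: a "no filter" member plus ``n_highpass`` IIR
    high-pass members with cutoffs evenly spaced over ``[low, high]`` of PRF
    (defaults 0.03 to 0.24)."""
    members: list[ClutterFilter] = [identity_filter()] if include_identity else []
    for fc in np.linspace(low, high, n_highpass):
        members.append(design_highpass(float(fc), order=order,
                                       projection_order=projection_order))
    return ClutterFilterBank(tuple(members))


def _polynomial_projection(x: np.ndarray, degree: int, axis: int) -> np.ndarray:
    """Component of ``x`` lying in the span of slow-time polynomials of the
    given degree (least squares along ``axis``)."""
    k = x.shape[axis]
    if degree == 0:
        return np.mean(x, axis=axis, keepdims=True) * np.ones_like(x)
    t = np.arange(k) / max(k - 1, 1)
    v = np.vander(t, degree + 1, increasing=True)
    proj = v @ np.linalg.pinv(v)  # (K, K) projection matrix
    xm = np.moveaxis(x, axis, -1)
    return np.moveaxis(xm @ proj.T, -1, axis)


def _apply_iir(filt: ClutterFilter, x: np.ndarray, axis: int) -> np.ndarray:
    if x.shape[axis] < filt.order + 1:
        raise InvalidArgumentError(
            f"slow-time length {x.shape[axis]} too short for order {filt.order}")
    resid = x - _polynomial_projection(x, filt.projection_order, axis)
    return signal.lfilter(filt.b, filt.a, resid, axis=axis)


def filter_slow_time(filt: ClutterFilter, series: np.ndarray) -> np.ndarray:
    """Filter a length-K complex slow-time sequence (last axis if N-D).

    The identity member returns the input unchanged; IIR members run the
    projection-initialized recursion so that any constant input maps to
    (numerically) zero output at every slow-time index.
    """
    series = np.asarray(series)
    if filt.is_identity:
        return series
    return _apply_iir(filt, series, axis=-1)


def apply_bank(bank: ClutterFilterBank, dataset: ChannelEnsemble) -> list[ChannelEnsemble]:
    """Pass a channel-data ensemble through every bank member.

    Returns one filtered :class:`ChannelEnsemble` per member, in bank order.
    Filtering runs per channel and per pixel along the slow-time axis and is
    linear in the input.
    """
    out = []
    for filt in bank:
        if filt.is_identity:
            data = dataset.data
        else:
            data = _apply_iir(filt, dataset.data, axis=3)
        out.append(ChannelEnsemble(data=data, grid=dataset.grid, acq=dataset.acq))
    return out
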