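"""Coherence-adaptive clutter filtering: per-pixel filter selection.

The adaptive pipeline passes each pixel's channel ensemble through every
member of a clutter filter bank, measures the short-lag spatial coherence
(SLSC) of the post-filter channel data, and selects, per pixel and frame,
the filter that maximizes (optionally weighted) SLSC.  The velocity estimate
at that filter's output is mapped to the final color flow image.  Ties break
toward the lowest cutoff (the identity "no filter" member first), the
conservative choice that preserves slow flow.

Pixels whose maximum SLSC falls below a fraction of the theoretical speckle
maximum can additionally be rejected (coherence thresholding) or forced to
the identity member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import SLSCStack, normalized_lag_correlations, theoretical_max_slsc
from .core import AcquisitionParams, ChannelEnsemble, InvalidArgumentError, PixelGrid
from .filters import ClutterFilter, ClutterFilterBank, apply_bank
from .priority import PriorityConfig, priority_encode
from .velocity import VelocityMap, beamsum, velocity_map

__all__ = ["FilterWeights", "SelectionMap", "ColorFlowImage", "select_filters",
           "cacf_image", "coherence_threshold", "conventional_image"]


@dataclass(frozen=True)
class FilterWeights:
    """Non-negative per-bank-member weights applied to SLSC before the
    argmax (uniform weights reduce to the plain maximum-coherence rule)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 1 or np.any(w < 0) or not np.any(w > 0):
            raise InvalidArgumentError("weights must be 1-D, >= 0 and not all zero")
        object.__setattr__(self, "weights", w)


@dataclass
class SelectionMap:
    """Per-pixel adaptive filter choice.

    ``index`` and ``cutoff_fraction`` have shape (n_axial, n_lateral,
    n_frames); ``max_slsc`` stores the (unweighted) SLSC of the chosen
    filter.
    """

    index: np.ndarray
    cutoff_fraction: np.ndarray
    max_slsc: np.ndarray


@dataclass
class ColorFlowImage:
    """Final color flow output: velocity plus the selection that produced it.

    ``rejected`` marks pixels zeroed by coherence thresholding or priority
    encoding.
    """

    velocity: VelocityMap
    selection: SelectionMap | None
    grid: PixelGrid
    acq: AcquisitionParams

    @property
    def rejected(self) -> np.ndarray:
        r = self.velocity.rejected
        return r if r is not None else np.zeros(self.velocity.v_hat.shape, bool)


def select_filters(stack: SLSCStack, bank: ClutterFilterBank,
                   weights: FilterWeights | None = None) -> SelectionMap:
    """Per-pixel argmax of (weighted) SLSC over the bank.

    Ties resolve toward the lowest cutoff: layers are in ascending-cutoff
    bank order and the first maximum wins.
    """
    values = stack.values
    if values.shape[0] != len(bank):
        raise InvalidArgumentError("stack layers do not match bank size")
    scored = values
    if weights is not None:
        if weights.weights.size != len(bank):
            raise InvalidArgumentError("weights length does not match bank size")
        scored = values * weights.weights[:, None, None, None]
    idx = np.argmax(scored, axis=0)  # first max -> lowest cutoff on ties
    max_slsc = np.take_along_axis(values, idx[None], axis=0)[0]
    return SelectionMap(index=idx,
                        cutoff_fraction=bank.cutoff_fractions[idx],
                        max_slsc=max_slsc)


def _stack_and_velocities(dataset: ChannelEnsemble, bank: ClutterFilterBank,
                          q: int, kernel_mm) -> tuple[SLSCStack, list[VelocityMap]]:
    slsc_layers = []
    vmaps = []
    # one member at a time: keeps only a single filtered copy in memory
    for filt in bank:
        filtered = apply_bank(ClutterFilterBank((filt,)), dataset)[0]
        d = np.moveaxis(filtered.data, 4, 2)  # (ax, lat, frame, M, K)
        r = normalized_lag_correlations(d, q)
        slsc_layers.append(np.sum(r.real, axis=-1))
        vmaps.append(velocity_map(beamsum(filtered), kernel_mm=kernel_mm))
    stack = SLSCStack(values=np.stack(slsc_layers), q=q,
                      cutoff_fractions=bank.cutoff_fractions)
    return stack, vmaps


def cacf_image(dataset: ChannelEnsemble, bank: ClutterFilterBank,
               q: int = 10, kernel_mm=None,
               weights: FilterWeights | None = None,
               coherence_threshold_fraction: float | None = None,
               below_threshold: str = "reject") -> ColorFlowImage:
    """Full adaptive pipeline on one dataset (all frames).

    filter bank -> per-filter SLSC from channel data + beamsum + velocity
    -> per-pixel selection -> gather velocities -> optional coherence
    thresholding.  ``below_threshold`` chooses what happens to sub-threshold
    pixels: ``"reject"`` zeroes and masks them, ``"no_filter"`` assigns the
    identity member's velocity instead.
    """
    stack, vmaps = _stack_and_velocities(dataset, bank, q, kernel_mm)
    selection = select_filters(stack, bank, weights)
    idx = selection.index
    v_all = np.stack([vm.v_hat for vm in vmaps])
    phi_all = np.stack([vm.phi_hat for vm in vmaps])
    v = np.take_along_axis(v_all, idx[None], axis=0)[0]
    phi = np.take_along_axis(phi_all, idx[None], axis=0)[0]
    vmap = VelocityMap(v_hat=v, phi_hat=phi, grid=dataset.grid, acq=dataset.acq,
                       rejected=np.zeros(v.shape, bool))
    image = ColorFlowImage(velocity=vmap, selection=selection,
                           grid=dataset.grid, acq=dataset.acq)
    if coherence_threshold_fraction is not None:
        if below_threshold == "no_filter":
            thr = coherence_threshold_fraction * theoretical_max_slsc(
                dataset.acq.n_channels, q)
            low = selection.max_slsc < thr
            id_layer = 0 if bank[0].is_identity else None
            if id_layer is None:
                raise InvalidArgumentError(
                    "below_threshold='no_filter' needs an identity bank member")
            vmap.v_hat = np.where(low, v_all[id_layer], vmap.v_hat)
            vmap.phi_hat = np.where(low, phi_all[id_layer], vmap.phi_hat)
            selection.index = np.where(low, id_layer, selection.index)
            selection.cutoff_fraction = bank.cutoff_fractions[selection.index]
        else:
            image = coherence_threshold(image, coherence_threshold_fraction,
                                        dataset.acq.n_channels, q)
    return image


def coherence_threshold(image: ColorFlowImage, fraction: float,
                        m_channels: int, q: int) -> ColorFlowImage:
    """Reject pixels whose maximum SLSC falls below ``fraction`` of the
    theoretical speckle maximum (velocity set to 0, mask set)."""
    if not 0 <= fraction <= 1:
        raise InvalidArgumentError("fraction must lie in [0, 1]")
    if image.selection is None:
        raise InvalidArgumentError("image carries no selection map")
    if fraction == 0:
        return image
    thr = fraction * theoretical_max_slsc(m_channels, q)
    low = image.selection.max_slsc < thr
    vmap = image.velocity.copy()
    vmap.v_hat = np.where(low, 0.0, vmap.v_hat)
    vmap.phi_hat = np.where(low, 0.0, vmap.phi_hat)
    prev = vmap.rejected if vmap.rejected is not None else np.zeros(low.shape, bool)
    vmap.rejected = prev | low
    return ColorFlowImage(velocity=vmap, selection=image.selection,
                          grid=image.grid, acq=image.acq)


def conventional_image(dataset: ChannelEnsemble, filt: ClutterFilter,
                       priority: PriorityConfig | None = None,
                       kernel_mm=None) -> ColorFlowImage:
    """Conventional single-filter color flow: beamsum of the filtered
    channel data -> velocity estimation -> optional priority encoding.  The
    baseline every adaptive comparison runs against."""
    bank = ClutterFilterBank((filt,))
    filtered = apply_bank(bank, dataset)[0]
    beams = beamsum(filtered)
    vmap = velocity_map(beams, kernel_mm=kernel_mm)
    vmap.rejected = np.zeros(vmap.v_hat.shape, bool)
    if priority is not None:
        vmap = priority_encode(vmap, beams, priority)
    return ColorFlowImage(velocity=vmap, selection=None,
                          grid=dataset.grid, acq=dataset.acq)
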