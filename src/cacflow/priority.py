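"""Priority encoding: variance and power thresholding of velocity maps.

The conventional post-estimation step that rejects unreliable color flow
pixels.  A pixel is set to 0 cm/s (and flagged in a rejection mask) when

* the population variance of velocity inside a spatial kernel exceeds a
  threshold sigma^2 (sigma given as a velocity spread in mm/s), or
* the kernel-mean ensemble power, normalized per frame by the image-maximum
  pixel ensemble power, falls below a threshold P in dB.

Both masks are computed from the pre-encoding inputs, so the two encodings
commute.  Kernels are truncated at image borders (the divisor counts only
pixels inside the image).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BeamEnsemble, InvalidArgumentError, ROI
from .velocity import VelocityMap, kernel_size_pixels

__all__ = ["PriorityConfig", "variance_encode", "power_encode", "priority_sweep"]


@dataclass(frozen=True)
class PriorityConfig:
    """Thresholds for priority encoding.

    ``sigma_mm_s`` is the velocity-spread threshold in mm/s (compared as
    sigma^2 against the kernel variance); ``power_db`` the normalized-power
    threshold in dB (<= 0).  Either may be None to disable that mask.
    ``kernel_mm`` defaults to a 2 x 2 mm kernel.
    """

    sigma_mm_s: float | None = None
    power_db: float | None = None
    kernel_mm: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        if self.sigma_mm_s is not None and self.sigma_mm_s < 0:
            raise InvalidArgumentError("sigma_mm_s must be >= 0 or None")
        if self.power_db is not None and self.power_db > 0:
            raise InvalidArgumentError("power_db must be <= 0 dB or None")
        if any(k <= 0 for k in self.kernel_mm):
            raise InvalidArgumentError("kernel extents must be positive")


def _kernel_mean_and_count(x: np.ndarray, size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Border-truncated kernel mean over the two leading grid axes."""
    if size == (1, 1):
        return x, np.ones_like(x)
    full = (size[0], size[1]) + (1,) * (x.ndim - 2)
    area = size[0] * size[1]
    s = ndimage.uniform_filter(x, full, mode="constant") * area
    cnt = ndimage.uniform_filter(np.ones_like(x), full, mode="constant") * area
    return s / cnt, cnt


def _apply_mask(vmap: VelocityMap, reject: np.ndarray) -> VelocityMap:
    out = vmap.copy()
    out.v_hat = np.where(reject, 0.0, out.v_hat)
    out.phi_hat = np.where(reject, 0.0, out.phi_hat)
    prev = out.rejected if out.rejected is not None else np.zeros_like(reject)
    out.rejected = prev | reject
    return out


def variance_mask(vmap: VelocityMap, config: PriorityConfig) -> np.ndarray:
    """Boolean mask of pixels whose kernel velocity variance exceeds sigma^2."""
    if config.sigma_mm_s is None:
        return np.zeros(vmap.v_hat.shape, bool)
    size = kernel_size_pixels(config.kernel_mm, vmap.grid)
    v_mm = vmap.v_hat * 10.0  # cm/s -> mm/s
    mean, _ = _kernel_mean_and_count(v_mm, size)
    mean_sq, _ = _kernel_mean_and_count(v_mm ** 2, size)
    var = np.maximum(mean_sq - mean ** 2, 0.0)  # population variance
    return var > config.sigma_mm_s ** 2


def power_mask(beams: BeamEnsemble, grid_map: VelocityMap,
               config: PriorityConfig) -> np.ndarray:
    """Boolean mask of pixels whose kernel-mean ensemble power falls below
    ``power_db`` relative to the per-frame image maximum pixel power."""
    if config.power_db is None:
        return np.zeros(grid_map.v_hat.shape, bool)
    size = kernel_size_pixels(config.kernel_mm, grid_map.grid)
    pix_power = np.sum(np.abs(beams.data) ** 2, axis=2)  # (ax, lat, frame)
    ref = pix_power.reshape(-1, pix_power.shape[-1]).max(axis=0)  # per frame
    if np.all(ref == 0):
        return np.ones(grid_map.v_hat.shape, bool)
    kmean, _ = _kernel_mean_and_count(pix_power, size)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(kmean / ref)
    return db < config.power_db


def variance_encode(vmap: VelocityMap, config: PriorityConfig) -> VelocityMap:
    """Zero out pixels failing the kernel-variance test; others unchanged."""
    return _apply_mask(vmap, variance_mask(vmap, config))


def power_encode(vmap: VelocityMap, beams: BeamEnsemble,
                 config: PriorityConfig) -> VelocityMap:
    """Zero out pixels failing the normalized-power test; others unchanged.

    ``beams`` must be the clutter-filtered beamsums used to form ``vmap``.
    """
    return _apply_mask(vmap, power_mask(beams, vmap, config))


def priority_encode(vmap: VelocityMap, beams: BeamEnsemble,
                    config: PriorityConfig) -> VelocityMap:
    """Variance then power encoding (order is immaterial: both masks are
    computed from the pre-encoding inputs)."""
    return power_encode(variance_encode(vmap, config), beams, config)


def priority_sweep(vmap: VelocityMap, beams: BeamEnsemble,
                   sigmas_mm_s: list[float], powers_db: list[float],
                   rois: dict[str, ROI] | None = None,
                   kernel_mm: tuple[float, float] = (2.0, 2.0),
                   ) -> tuple[dict[tuple[float, float], VelocityMap], pd.DataFrame]:
    """Encode a velocity map for every (sigma, P) threshold pair.

    Returns the encoded map per pair and a tidy summary frame with one row
    per (sigma, P, roi): mean encoded velocity over the ROI (rejected pixels
    count as 0 cm/s, all frames pooled) and the retained-pixel fraction.
    """
    maps: dict[tuple[float, float], VelocityMap] = {}
    rows = []
    rois = rois or {"image": ROI(mask=np.ones(vmap.grid.shape, bool))}
    for sig, p in product(sigmas_mm_s, powers_db):
        cfg = PriorityConfig(sigma_mm_s=sig, power_db=p, kernel_mm=kernel_mm)
        enc = priority_encode(vmap, beams, cfg)
        maps[(sig, p)] = enc
        for name, roi in rois.items():
            sel = roi.mask_for(vmap.grid)
            v = enc.v_hat[sel]
            kept = ~enc.rejected[sel]
            rows.append({
                "sigma_mm_s": sig, "power_db": p, "roi": name,
                "mean_velocity_cm_s": float(v.mean()),
                "retained_fraction": float(kept.mean()),
            })
    return maps, pd.DataFrame(rows)
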