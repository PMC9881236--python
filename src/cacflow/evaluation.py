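"""ROI statistics, B-mode contrast, and the computational-cost model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeamEnsemble, InvalidArgumentError, ROI

__all__ = ["RoiSummary", "roi_stats", "envelope_image", "contrast_db",
           "FlopModel", "flop_ratio", "acquisition_duration"]


@dataclass(frozen=True)
class RoiSummary:
    """Velocity statistics over an ROI for one frame.

    ``std`` is the population (1/N) standard deviation over the ROI pixels;
    ``stderr = std / sqrt(count)`` is the spatial standard error.
    """

    mean: float
    std: float
    stderr: float
    count: int
    frame: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InvalidArgumentError("pixel count cannot be negative")


def roi_stats(image_or_map, roi: ROI,
              include_rejected: bool = False) -> list[RoiSummary]:
    """Per-frame mean/std/stderr of velocity over an ROI.

    Accepts a :class:`~cacflow.velocity.VelocityMap` or
    :class:`~cacflow.cacf.ColorFlowImage`.  Pixels flagged as rejected are
    excluded by default (their zeros are placeholders, not measurements);
    the reported ``count`` always refers to the pixels actually averaged.
    """
    vmap = getattr(image_or_map, "velocity", image_or_map)
    mask = roi.mask_for(vmap.grid)
    rejected = vmap.rejected
    out = []
    for frame in range(vmap.n_frames):
        sel = mask.copy()
        if rejected is not None and not include_rejected:
            sel &= ~rejected[..., frame]
        if not sel.any():  # every ROI pixel rejected this frame
            out.append(RoiSummary(mean=0.0, std=0.0, stderr=0.0, count=0, frame=frame))
            continue
        v = vmap.v_hat[..., frame][sel]
        std = float(v.std())  # population normalization
        out.append(RoiSummary(mean=float(v.mean()), std=std,
                              stderr=std / np.sqrt(v.size),
                              count=int(v.size), frame=frame))
    return out


def roi_stats_frame(summaries: list[RoiSummary]) -> pd.DataFrame:
    """Tidy DataFrame view of per-frame ROI summaries."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def envelope_image(beams: BeamEnsemble) -> np.ndarray:
    """Per-pixel mean beamsum magnitude over slow time and frames (the
    B-mode-style envelope used for contrast measurements)."""
    return np.mean(np.abs(beams.data), axis=(2, 3))


def contrast_db(envelope: np.ndarray, roi_a: ROI, roi_b: ROI, grid) -> float:
    """Amplitude contrast ``20 log10(mean_a / mean_b)`` between two ROIs of a
    per-pixel envelope image (e.g. anechoic vs speckle)."""
    mean_a = float(envelope[roi_a.mask_for(grid)].mean())
    mean_b = float(envelope[roi_b.mask_for(grid)].mean())
    if mean_b <= 0:
        raise InvalidArgumentError("reference ROI mean must be positive")
    return 20.0 * np.log10(mean_a / mean_b)


@dataclass(frozen=True)
class FlopModel:
    """Leading-order operation counts for the adaptive pipeline.

    M channels, K slow-time samples, F clutter filters.  Per pixel the
    adaptive path costs on the order of ``F K M^2`` (coherence) +
    ``F K^2 M`` (filtering) + ``F K M`` (channel sums); the conventional
    path costs ``K M + K^2`` (one channel sum, one filter).
    """

    m_channels: int
    k_samples: int
    n_filters: int

    def __post_init__(self) -> None:
        if min(self.m_channels, self.k_samples, self.n_filters) < 1:
            raise InvalidArgumentError("model dimensions must be >= 1")


def flop_ratio(model: FlopModel) -> float:
    """Adaptive-over-conventional FLOP ratio
    ``(F K M^2 + F K^2 M + F K M) / (K M + K^2)``."""
    m, k, f = model.m_channels, model.k_samples, model.n_filters
    return (f * k * m ** 2 + f * k ** 2 * m + f * k * m) / (k * m + k ** 2)


def acquisition_duration(n_frames: int, frame_rate_hz: float) -> float:
    """Total acquisition time in seconds: ``n_frames / frame_rate``."""
    if n_frames < 0 or frame_rate_hz <= 0:
        raise InvalidArgumentError("need n_frames >= 0 and frame_rate > 0")
    return n_frames / frame_rate_hz
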