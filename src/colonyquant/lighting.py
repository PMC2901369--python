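"""Lighting-gradient correction by regression toward the median background.

Using the pseudo-empty plate as a lighting map, every pixel is scaled by
``R_corr = I_med / I_pe`` where ``I_pe`` is the pseudo-empty intensity at
that pixel and ``I_med`` the median background intensity over the grid
area.  Applying the same ratio to the original image flattens the lighting
field while preserving culture contrast, without ever photographing a dummy
(empty) plate.  The method assumes a multiplicative lighting model and
non-saturated source images; corrected values are capped at 255 and
saturation events are logged as a quality warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .background import PseudoEmptyPlate
from .raster import GridSpec, grid_bbox

__all__ = ["CorrectionMap", "median_background", "build_correction", "apply_correction"]

log = logging.getLogger(__name__)

#: Floor applied to pseudo-empty intensities before division.
EPSILON = 1.0
#: Ratios outside this band are clipped (pathological dark/bright pixels).
RATIO_CLIP = (0.2, 5.0)


@dataclass(frozen=True)
class CorrectionMap:
    """Per-pixel correction ratios plus the median background they target."""

    ratios: np.ndarray  # positive float64 raster
    i_med: float
    n_clipped: int = 0


def median_background(pe: PseudoEmptyPlate, spec: GridSpec) -> float:
    """Median pseudo-empty intensity over the grid bounding box."""
    ys, xs = grid_bbox(spec, pe.pixels.shape)
    return float(np.median(pe.pixels[ys, xs]))


def build_correction(pe: PseudoEmptyPlate, i_med: float) -> CorrectionMap:
    """Correction ratios ``i_med / max(I_pe, eps)``, clipped to a safe band."""
    if i_med <= 0:
        raise ValueError("median background intensity must be positive")
    raw = i_med / np.maximum(pe.pixels, EPSILON)
    ratios = np.clip(raw, *RATIO_CLIP)
    n_clipped = int(np.count_nonzero(raw != ratios))
    if n_clipped:
        log.warning("correction map: %d ratios clipped to %s", n_clipped, RATIO_CLIP)
    return CorrectionMap(ratios=ratios, i_med=float(i_med), n_clipped=n_clipped)


def apply_correction(img: np.ndarray, cmap: CorrectionMap) -> np.ndarray:
    """Scale an image by the correction map, capping at 255.

    For RGB input the greyscale-derived ratio is applied to all three
    channels, keeping colour measurements comparable across the plate.
    """
    img = np.asarray(img, dtype=np.float64)
    ratios = cmap.ratios
    if img.ndim == 3:
        ratios = ratios[..., None]
    if ratios.shape[:2] != img.shape[:2]:
        raise ValueError("correction map dimensions do not match the image")
    corrected = ratios * img
    n_sat = int(np.count_nonzero(corrected > 255.0))
    if n_sat:
        log.warning("lighting correction saturated %d pixel values at 255", n_sat)
    return np.minimum(corrected, 255.0)
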