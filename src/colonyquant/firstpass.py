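"""Fast first-pass segmentation: Sobel gradients and per-tile thresholding.

This stage only needs to be *sensitive*: every pixel carrying culture signal
must be flagged, while agar pixels wrongly flagged as culture are harmless
(they are cut out and re-interpolated when the pseudo-empty plate is built).
Per tile, the pixels whose Sobel gradient magnitude is in the top 5% mark
the steep culture edges; the tile is then re-thresholded at the intensity
below which the darkest 33% of those masked pixels lie, so that whole
colony interiors — not just their edges — survive.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage as ndi

from .raster import TileBox, tile_slices

__all__ = [
    "sobel_gradient",
    "nearest_rank_cutoff",
    "gradient_mask",
    "local_threshold",
    "firstpass_masks",
]

log = logging.getLogger(__name__)


def sobel_gradient(grey: np.ndarray) -> np.ndarray:
    """Gradient magnitude map ``sqrt(Gx^2 + Gy^2)`` of the 3x3 Sobel kernels.

    Borders are handled by edge replication.  Constant images map to an
    identically zero field.
    """
    grey = np.asarray(grey, dtype=np.float64)
    if grey.ndim != 2:
        raise ValueError("sobel_gradient expects a greyscale raster")
    if grey.shape[0] < 3 or grey.shape[1] < 3:
        raise ValueError("image smaller than the 3x3 Sobel kernel")
    gx = ndi.sobel(grey, axis=1, mode="nearest")
    gy = ndi.sobel(grey, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def nearest_rank_cutoff(values: np.ndarray, fraction: float) -> float:
    """Nearest-rank percentile: the value below-or-at which ``fraction`` of
    ``values`` lies, i.e. the element of rank ``ceil(fraction * n)`` (1-based)
    in ascending order.  ``fraction=0`` maps to the minimum.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n == 0:
        raise ValueError("cannot take a percentile of zero values")
    rank = max(1, math.ceil(fraction * n))
    idx = min(rank, n) - 1
    return float(np.partition(values, idx)[idx])


def gradient_mask(
    gm: np.ndarray, tile: TileBox, keep_fraction: float = 0.05
) -> np.ndarray:
    """Tile-local mask of the steepest gradients.

    True exactly for tile pixels whose gradient is *strictly above* the
    ``(1 - keep_fraction)`` nearest-rank percentile of the tile's gradients,
    so ties resolve toward background and at most ``ceil(keep_fraction * n)``
    pixels survive.
    """
    ys, xs = tile_slices(tile, gm.shape)
    sub = np.asarray(gm, dtype=np.float64)[ys, xs]
    if sub.size == 0:
        raise ValueError(f"tile ({tile.row},{tile.col}) has no pixels inside the image")
    cutoff = nearest_rank_cutoff(sub, 1.0 - keep_fraction)
    return sub > cutoff


def local_threshold(
    grey: np.ndarray,
    tile: TileBox,
    mask: np.ndarray,
    dark_fraction: float = 0.33,
) -> np.ndarray:
    """First-pass culture classification of one tile.

    The intensity cutoff is the nearest-rank ``dark_fraction`` percentile of
    the *masked* (high-gradient) pixel intensities; the whole tile is then
    thresholded at that cutoff — every tile pixel strictly brighter than it
    becomes culture, so colony interiors survive along with their edges.
    A tile with no masked pixels is returned all-background.
    """
    ys, xs = tile_slices(tile, grey.shape)
    sub = np.asarray(grey, dtype=np.float64)[ys, xs]
    if mask.shape != sub.shape:
        raise ValueError("mask shape does not match the tile")
    masked_vals = sub[mask]
    if masked_vals.size == 0:
        log.warning(
            "tile (%d,%d): no high-gradient pixels; first pass marks no culture",
            tile.row,
            tile.col,
        )
        return np.zeros(sub.shape, dtype=bool)
    cutoff = nearest_rank_cutoff(masked_vals, dark_fraction)
    return sub > cutoff


def firstpass_masks(
    grey: np.ndarray,
    tiles: list[TileBox],
    keep_fraction: float = 0.05,
    dark_fraction: float = 0.33,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the first pass over every tile of a plate.

    Returns ``(culture, grad_mask, gradient_map)``: plate-wide boolean
    culture mask, plate-wide boolean high-gradient mask (later reused as the
    granularity measure), and the Sobel gradient magnitude map.  Pixels
    outside every tile stay background.
    """
    gm = sobel_gradient(grey)
    culture = np.zeros(grey.shape, dtype=bool)
    gmask = np.zeros(grey.shape, dtype=bool)
    for tile in tiles:
        ys, xs = tile_slices(tile, grey.shape)
        tile_gmask = gradient_mask(gm, tile, keep_fraction)
        tile_culture = local_threshold(grey, tile, tile_gmask, dark_fraction)
        gmask[ys, xs] |= tile_gmask
        culture[ys, xs] |= tile_culture
    return culture, gmask, gm
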