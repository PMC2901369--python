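"""Pseudo-empty plate reconstruction.

The pseudo-empty plate is the best estimate of what the agar plate would
look like with no cultures on it, and serves as the lighting map for
gradient correction.  First-pass culture pixels are cut out of a strongly
smoothed greyscale image and each gap is filled by linear interpolation
between edge values found on either side.  Because reflective halos and
through-agar reflections leave a bright strip just outside a culture, the
edge value is not the immediately adjacent pixel but the *darkest* pixel
within roughly one culture radius (``x_dim/2``) of the gap.  The scan is
performed twice — along rows and along columns — and the two filled images
are merged by pointwise minimum, which suppresses the occasional bright
island inside an irregular culture from leaking into the fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .raster import GridSpec, effective_dims

__all__ = ["PseudoEmptyPlate", "smooth", "find_edge_value", "fill_gaps", "build_pseudo_empty"]


@dataclass(frozen=True)
class PseudoEmptyPlate:
    """Reconstructed empty-plate raster plus per-pixel provenance."""

    pixels: np.ndarray  # float64 greyscale raster, [0, 255]
    interpolated: np.ndarray  # bool: True where the value was filled in


def smooth(grey: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with standard deviation ``sigma`` pixels (edge-replicated).

    Strong smoothing (default ``x_dim/4`` in :func:`build_pseudo_empty`)
    averages out pixel noise at colony scale while leaving plate-scale
    lighting gradients intact, so that interpolation edge values are not
    dominated by extreme noise pixels.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(grey, dtype=np.float64), sigma, mode="nearest")


def find_edge_value(
    line: np.ndarray,
    culture: np.ndarray,
    gap_start: int,
    gap_stop: int,
    direction: int,
    search_dist: int,
) -> float | None:
    """Darkest observed pixel near one side of a gap on a 1-D scan line.

    ``direction`` is -1 for the side before ``gap_start`` and +1 for the side
    after ``gap_stop`` (exclusive).  The window holds up to ``search_dist``
    pixel positions moving away from the gap, truncated at the image border;
    pixels belonging to other culture gaps are skipped.  Returns ``None``
    when no observed pixel exists in the window (the caller then falls back
    to the opposite side).
    """
    if search_dist < 1:
        raise ValueError("search_dist must be >= 1")
    n = line.shape[0]
    if direction < 0:
        lo, hi = max(0, gap_start - search_dist), gap_start
    else:
        lo, hi = gap_stop, min(n, gap_stop + search_dist)
    if lo >= hi:
        return None
    window = line[lo:hi]
    observed = window[~culture[lo:hi]]
    if observed.size == 0:
        return None
    return float(observed.min())


def _fill_line(line: np.ndarray, culture: np.ndarray, search_dist: int, fallback: float) -> None:
    """Fill every maximal culture run on one scan line, in place."""
    n = line.shape[0]
    padded = np.concatenate(([False], culture, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    for a, b in zip(starts, stops):
        left = find_edge_value(line, culture, a, b, -1, search_dist)
        right = find_edge_value(line, culture, a, b, +1, search_dist)
        if left is None and right is None:
            left = right = fallback
        elif left is None:
            left = right
        elif right is None:
            right = left
        w = b - a
        line[a:b] = np.linspace(left, right, w + 2)[1:-1]


def fill_gaps(
    grey: np.ndarray,
    culture: np.ndarray,
    axis: str,
    search_dist: int,
    fallback: float | None = None,
) -> np.ndarray:
    """Cut culture pixels out of a smoothed raster and fill gaps along one axis.

    ``axis`` is ``"horizontal"`` (scan along rows) or ``"vertical"`` (scan
    along columns).  Observed pixels are returned unchanged.  A scan line
    that is entirely culture is filled with ``fallback`` (by default the
    plate-wide median of observed pixels).
    """
    grey = np.asarray(grey, dtype=np.float64)
    culture = np.asarray(culture, dtype=bool)
    if culture.shape != grey.shape:
        raise ValueError("culture mask shape does not match the raster")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    if fallback is None:
        observed = grey[~culture]
        fallback = float(np.median(observed)) if observed.size else float(np.median(grey))
    out = grey.copy()
    if axis == "horizontal":
        for i in range(out.shape[0]):
            if culture[i].any():
                _fill_line(out[i], culture[i], search_dist, fallback)
    else:
        outT = out.T
        cultureT = culture.T
        for j in range(outT.shape[0]):
            if cultureT[j].any():
                _fill_line(outT[j], cultureT[j], search_dist, fallback)
    return out


def build_pseudo_empty(
    grey: np.ndarray,
    culture: np.ndarray,
    spec: GridSpec,
    sigma: float | None = None,
) -> PseudoEmptyPlate:
    """Construct the pseudo-empty plate from a greyscale image and first-pass mask.

    The greyscale image is strongly smoothed (``sigma`` defaults to
    ``x_dim/4``), culture pixels are cut out, and gaps are filled twice on a
    fresh smoothed copy each time: scanning horizontally with search distance
    ``x_dim/2`` and vertically with ``y_dim/2``.  The two directional fills
    are merged by pointwise minimum.
    """
    x_dim, y_dim = effective_dims(spec)
    if sigma is None:
        sigma = max(x_dim / 4.0, 0.5)
    sm = smooth(grey, sigma)
    observed = sm[~culture]
    fallback = float(np.median(observed)) if observed.size else float(np.median(sm))
    h_dist = max(1, int(round(x_dim / 2.0)))
    v_dist = max(1, int(round(y_dim / 2.0)))
    horiz = fill_gaps(sm, culture, "horizontal", h_dist, fallback)
    vert = fill_gaps(sm.copy(), culture, "vertical", v_dist, fallback)
    merged = np.minimum(horiz, vert)
    return PseudoEmptyPlate(pixels=merged, interpolated=np.asarray(culture, dtype=bool).copy())
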