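"""Tile localisation refinement and per-culture measurements.

Starting from the calibrated lattice, each tile's position (never its size)
is refined by brute-force search over a 20x20 pixel window, minimising the
number of culture pixels sitting on the tile's one-pixel perimeter — a
well-centred tile has its culture strictly inside.  The refined tile then
yields the culture's area, integrated optical density (IOD), a whole-tile
IOD variant, granularity (high-gradient pixel count, a texture measure)
and mean culture / agar colour, written row-major to a tab-delimited table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .raster import GridSpec, TileBox, tile_slices

__all__ = [
    "CultureMeasures",
    "refine_tile",
    "measure_tile",
    "quantify_plate",
    "measures_to_frame",
    "write_measures",
    "COLUMNS",
]

COLUMNS = [
    "image_id", "row", "col", "x", "y", "width", "height",
    "area", "iod", "tile_iod", "granularity",
    "r_culture", "g_culture", "b_culture",
    "r_agar", "g_agar", "b_agar", "edge_flag",
]


@dataclass(frozen=True)
class CultureMeasures:
    """All quantities measured for one culture tile."""

    row: int
    col: int
    x: int
    y: int
    width: int
    height: int
    area: int
    iod: float
    tile_iod: float
    granularity: int
    culture_rgb: tuple[float, float, float] | None  # None when area == 0
    agar_rgb: tuple[float, float, float] | None
    edge: bool = False


def _boxsum(prefix: np.ndarray, y0: int, x0: int, y1: int, x1: int) -> int:
    """Sum of a clipped half-open box from a 2-D prefix-sum table."""
    h, w = prefix.shape[0] - 1, prefix.shape[1] - 1
    y0 = min(max(y0, 0), h)
    y1 = min(max(y1, 0), h)
    x0 = min(max(x0, 0), w)
    x1 = min(max(x1, 0), w)
    if y0 >= y1 or x0 >= x1:
        return 0
    return int(prefix[y1, x1] - prefix[y0, x1] - prefix[y1, x0] + prefix[y0, x0])


def _perimeter_count(prefix: np.ndarray, x: int, y: int, w: int, h: int) -> int:
    full = _boxsum(prefix, y, x, y + h, x + w)
    interior = _boxsum(prefix, y + 1, x + 1, y + h - 1, x + w - 1)
    return full - interior


def refine_tile(tile: TileBox, mask: np.ndarray, search: int = 10,
                _prefix: np.ndarray | None = None) -> TileBox:
    """Exhaustive search for the tile offset minimising edge culture pixels.

    Offsets range over ``[-search, search - 1]`` in both directions (a 20x20
    lattice at the default).  Ties are broken by smallest Euclidean offset,
    then by row-major order over the offset lattice.  Width and height are
    unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    prefix = _prefix
    if prefix is None:
        prefix = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(mask, axis=0), axis=1, out=prefix[1:, 1:])
    best_key = None
    best_off = (0, 0)
    for dy in range(-search, search):
        for dx in range(-search, search):
            score = _perimeter_count(prefix, tile.x + dx, tile.y + dy, tile.width, tile.height)
            key = (score, dx * dx + dy * dy)
            if best_key is None or key < best_key:
                best_key = key
                best_off = (dy, dx)
    dy, dx = best_off
    return replace(tile, x=tile.x + dx, y=tile.y + dy)


def measure_tile(
    tile: TileBox,
    mask: np.ndarray,
    corrected: np.ndarray,
    original: np.ndarray,
    grad_mask: np.ndarray,
    i_med: float,
    colour: bool = True,
    edge: bool = False,
) -> CultureMeasures:
    """All measurements for one (already refined) tile.

    * ``area``: culture-pixel count inside the tile.
    * ``iod``: sum of ``max(I_corr - i_med, 0)`` over culture pixels —
      background-subtracted corrected intensity, clamped per pixel so bright
      agar cannot contribute negative density.
    * ``tile_iod``: the same sum over *all* tile pixels, clamped at 0 as a
      whole; an alternative density measure robust to segmentation misses.
    * ``granularity``: count of high-gradient pixels in the tile.
    * ``culture_rgb`` / ``agar_rgb``: mean original-image colour over
      culture / non-culture tile pixels (``None`` when the set is empty).
    """
    ys, xs = tile_slices(tile, mask.shape)
    m = mask[ys, xs]
    corr = np.asarray(corrected, dtype=np.float64)[ys, xs]
    area = int(m.sum())
    excess = np.maximum(corr - i_med, 0.0)
    iod = float(excess[m].sum())
    tile_iod = max(float((corr - i_med).sum()), 0.0)
    granularity = int(np.asarray(grad_mask, dtype=bool)[ys, xs].sum())

    culture_rgb = agar_rgb = None
    if colour:
        rgb = np.asarray(original, dtype=np.float64)[ys, xs]
        if area > 0:
            culture_rgb = tuple(float(v) for v in rgb[m].mean(axis=0))
        if (~m).any():
            agar_rgb = tuple(float(v) for v in rgb[~m].mean(axis=0))
    return CultureMeasures(
        row=tile.row, col=tile.col, x=tile.x, y=tile.y,
        width=tile.width, height=tile.height,
        area=area, iod=iod, tile_iod=tile_iod, granularity=granularity,
        culture_rgb=culture_rgb, agar_rgb=agar_rgb, edge=edge,
    )


def quantify_plate(
    tiles: list[TileBox],
    mask: np.ndarray,
    corrected: np.ndarray,
    original: np.ndarray,
    grad_mask: np.ndarray,
    i_med: float,
    spec: GridSpec,
    search: int = 10,
    colour: bool = True,
) -> list[CultureMeasures]:
    """Refine every tile on the final mask, then measure it; row-major order.

    Edge tiles (first/last row or column) are measured normally but flagged:
    edge cultures enjoy a nutrient advantage and should be non-experimental
    on dense formats.
    """
    mask = np.asarray(mask, dtype=bool)
    prefix = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=prefix[1:, 1:])
    out = []
    for tile in sorted(tiles, key=lambda t: (t.row, t.col)):
        refined = refine_tile(tile, mask, search=search, _prefix=prefix)
        edge = (
            tile.row == 0 or tile.col == 0
            or tile.row == spec.n_rows - 1 or tile.col == spec.n_cols - 1
        )
        out.append(
            measure_tile(refined, mask, corrected, original, grad_mask, i_med,
                         colour=colour, edge=edge)
        )
    return out


def measures_to_frame(measures: list[CultureMeasures], image_id: str) -> pd.DataFrame:
    """Assemble measurements into the standard tab-delimited table layout."""
    rows = []
    for m in measures:
        cr = m.culture_rgb or (np.nan, np.nan, np.nan)
        ar = m.agar_rgb or (np.nan, np.nan, np.nan)
        rows.append({
            "image_id": image_id, "row": m.row, "col": m.col,
            "x": m.x, "y": m.y, "width": m.width, "height": m.height,
            "area": m.area, "iod": m.iod, "tile_iod": m.tile_iod,
            "granularity": m.granularity,
            "r_culture": cr[0], "g_culture": cr[1], "b_culture": cr[2],
            "r_agar": ar[0], "g_agar": ar[1], "b_agar": ar[2],
            "edge_flag": int(m.edge),
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_measures(frame: pd.DataFrame, path) -> None:
    """Write the measurement table as tab-delimited text with NA markers."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4f")
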