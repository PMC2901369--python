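"""Image and grid-geometry primitives for arrayed-culture plates.

Plate photographs are held as plain NumPy rasters with intensities on the
fixed 8-bit scale [0, 255] (stored as float64 so downstream corrections do
not lose precision): an RGB raster has shape ``(height, width, 3)``, a
greyscale raster ``(height, width)``.  The culture array itself is described
by a :class:`GridSpec` — the user's calibration of the rectangular grid —
from which the initial rectangular tile per culture is derived.

Coordinate convention: 0-based pixel indices, ``x`` is the column measured
from the left edge, ``y`` the row measured from the top.  A tile occupies
the half-open box ``[x, x+width) x [y, y+height)``.
"""

from __future__ import annotations

import configparser
import io
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GridSpec",
    "TileBox",
    "load_image",
    "save_image",
    "to_greyscale",
    "effective_dims",
    "init_tiles",
    "grid_bbox",
    "tile_slices",
    "read_grid_config",
    "grid_for_image",
    "CalibrationError",
]

#: ITU-R BT.601 luma weights used for RGB -> greyscale conversion.
GREY_WEIGHTS = (0.299, 0.587, 0.114)


class CalibrationError(ValueError):
    """Raised when a grid calibration is geometrically impossible."""


@dataclass(frozen=True)
class GridSpec:
    """User calibration of the culture grid.

    Parameters
    ----------
    n_rows, n_cols:
        Number of grid rows / columns (48, 96, 384, 768, 1536 format or any
        other rectangular layout).
    x_tl, y_tl:
        Pixel coordinates of the centre of the top-left culture.
    x_br, y_br:
        Pixel coordinates of the centre of the bottom-right culture.
    x_dim, y_dim:
        Tile dimensions in pixels.  When the corresponding count is greater
        than one these are recomputed from the corner-centre spacing (see
        :func:`effective_dims`); for a single row/column the supplied value
        is used unchanged and is then mandatory.
    """

    n_rows: int
    n_cols: int
    x_tl: float
    y_tl: float
    x_br: float
    y_br: float
    x_dim: float | None = None
    y_dim: float | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise CalibrationError("grid must have at least one row and one column")
        if self.x_tl > self.x_br or self.y_tl > self.y_br:
            raise CalibrationError("top-left centre must not lie beyond bottom-right centre")
        if self.n_cols > 1 and self.x_tl == self.x_br:
            raise CalibrationError("x_tl == x_br with more than one column")
        if self.n_rows > 1 and self.y_tl == self.y_br:
            raise CalibrationError("y_tl == y_br with more than one row")


@dataclass(frozen=True)
class TileBox:
    """One culture's rectangular tile: grid position plus pixel geometry."""

    row: int
    col: int
    x: int
    y: int
    width: int
    height: int


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image (JPEG/PNG/TIFF) as a float64 RGB raster.

    Greyscale files are promoted to three identical planes; an alpha channel
    is dropped.  Anything that is not 8 bits per channel is rejected.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types
        raise OSError(f"cannot read image file {path!s}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise OSError(f"unsupported bit depth {arr.dtype} in {path!s}: expected 8-bit")
    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"unsupported image layout {arr.shape} in {path!s}")
    return arr.astype(np.float64)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a raster (grey or RGB, [0,255] floats) as an 8-bit image file."""
    out = np.clip(np.round(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def to_greyscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to greyscale with BT.601 luma weights."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("to_greyscale expects an RGB raster of shape (h, w, 3)")
    wr, wg, wb = GREY_WEIGHTS
    return wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]


def _round_half_away(v: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def effective_dims(spec: GridSpec) -> tuple[float, float]:
    """Tile dimensions implied by the calibration.

    With more than one column the horizontal dimension is the corner-centre
    spacing ``(x_br - x_tl) / (n_cols - 1)``, so that tiles exactly abut;
    analogously for rows.  A single-row/column grid needs the user-supplied
    dimension.
    """
    if spec.n_cols > 1:
        x_dim = (spec.x_br - spec.x_tl) / (spec.n_cols - 1)
    else:
        if spec.x_dim is None:
            raise CalibrationError("x_dim is required when n_cols == 1")
        x_dim = float(spec.x_dim)
    if spec.n_rows > 1:
        y_dim = (spec.y_br - spec.y_tl) / (spec.n_rows - 1)
    else:
        if spec.y_dim is None:
            raise CalibrationError("y_dim is required when n_rows == 1")
        y_dim = float(spec.y_dim)
    if x_dim <= 0 or y_dim <= 0:
        raise CalibrationError(f"calibration implies non-positive tile size ({x_dim}, {y_dim})")
    return x_dim, y_dim


def init_tiles(spec: GridSpec) -> list[TileBox]:
    """Initial tile lattice from the grid calibration, row-major order.

    The top-left tile's corner starts half a tile up-left of the top-left
    culture centre (``x_start = x_tl - x_dim/2``) and the lattice steps
    ``x_dim`` horizontally and ``y_dim`` vertically.  Coordinates are rounded
    (half away from zero) once, at construction.
    """
    x_dim, y_dim = effective_dims(spec)
    x_start = spec.x_tl - x_dim / 2.0
    y_start = spec.y_tl - y_dim / 2.0
    w = max(1, _round_half_away(x_dim))
    h = max(1, _round_half_away(y_dim))
    tiles: list[TileBox] = []
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            tiles.append(
                TileBox(
                    row=i,
                    col=j,
                    x=_round_half_away(x_start + j * x_dim),
                    y=_round_half_away(y_start + i * y_dim),
                    width=w,
                    height=h,
                )
            )
    return tiles


def tile_slices(tile: TileBox, shape: tuple[int, ...]) -> tuple[slice, slice]:
    """Clamped (row, column) slices for pixel access within an image.

    Tiles keep their nominal geometry; only pixel access is clamped to the
    image, so a tile nudged past the border never raises.
    """
    h, w = shape[0], shape[1]
    y0 = min(max(tile.y, 0), h)
    y1 = min(max(tile.y + tile.height, 0), h)
    x0 = min(max(tile.x, 0), w)
    x1 = min(max(tile.x + tile.width, 0), w)
    return slice(y0, y1), slice(x0, x1)


def grid_bbox(spec: GridSpec, shape: tuple[int, ...]) -> tuple[slice, slice]:
    """Bounding box of the full tile lattice, clamped to the image.

    This is the "user-estimated area containing growing spots" used for the
    median background intensity and the segmentation histogram.
    """
    tiles = init_tiles(spec)
    x0 = min(t.x for t in tiles)
    y0 = min(t.y for t in tiles)
    x1 = max(t.x + t.width for t in tiles)
    y1 = max(t.y + t.height for t in tiles)
    h, w = shape[0], shape[1]
    ys = slice(min(max(y0, 0), h), min(max(y1, 0), h))
    xs = slice(min(max(x0, 0), w), min(max(x1, 0), w))
    if ys.start >= ys.stop or xs.start >= xs.stop:
        raise CalibrationError("grid bounding box does not intersect the image")
    return ys, xs


# ---------------------------------------------------------------------------
# Plain-text grid calibration files
# ---------------------------------------------------------------------------

_KEYS = ("nrows", "ncols", "xtl", "ytl", "xbr", "ybr")


def _spec_from_items(items: dict[str, str], source: str) -> GridSpec:
    missing = [k for k in _KEYS if k not in items]
    if missing:
        raise CalibrationError(f"grid config block {source!r} is missing keys: {missing}")
    return GridSpec(
        n_rows=int(items["nrows"]),
        n_cols=int(items["ncols"]),
        x_tl=float(items["xtl"]),
        y_tl=float(items["ytl"]),
        x_br=float(items["xbr"]),
        y_br=float(items["ybr"]),
        x_dim=float(items["xdim"]) if "xdim" in items else None,
        y_dim=float(items["ydim"]) if "ydim" in items else None,
    )


def read_grid_config(path: str | Path) -> dict[str, GridSpec]:
    """Parse a plain-text ``key = value`` grid calibration file.

    The file holds one default block (no header, or ``[default]``) that
    applies to a whole batch, optionally followed by ``[image-name]``
    sections overriding it for individual images.  Recognised keys:
    ``nrows, ncols, xtl, ytl, xbr, ybr`` and optional ``xdim, ydim``.
    """
    text = Path(path).read_text()
    if not text.lstrip().startswith("["):
        text = "[default]\n" + text
    cp = configparser.ConfigParser()
    cp.read_file(io.StringIO(text), source=str(path))
    out: dict[str, GridSpec] = {}
    for section in cp.sections():
        items = {k.lower(): v for k, v in cp.items(section)}
        out[section] = _spec_from_items(items, section)
    if not out:
        raise CalibrationError(f"no grid calibration found in {path!s}")
    return out


def grid_for_image(configs: dict[str, GridSpec], image_path: str | Path) -> GridSpec:
    """Pick the calibration block for an image: exact name, stem, or default."""
    p = Path(image_path)
    for key in (p.name, p.stem):
        if key in configs:
            return configs[key]
    if "default" in configs:
        return configs["default"]
    raise CalibrationError(f"no grid calibration for image {p.name!r} and no default block")
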