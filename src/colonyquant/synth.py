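"""Seeded synthetic plate-image generator with exact ground truth.

Emulates the phenomenology of real plate photographs that the analysis
pipeline must survive: smooth multiplicative lighting gradients, noisy agar
background, cultures ranging from barely-visible dilute spots (irregular
unions of sub-spots) to dense opaque discs, reflective halos around
cultures, and glare from the plate walls.  Every plate carries a sidecar
:class:`GroundTruth` (per-position pixel masks as a label map, true areas
and true integrated densities, plus the noiseless background field) so that
each pipeline stage can be tested against known truth.

Rendering model::

    image = (agar + sum(colony profiles) + halos + glare) * gradient + noise

clipped to [0, 255].  The lighting model is multiplicative, matching the
ratio-based correction it is used to exercise.  Identical specs (including
the seed) render bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .growth import LogisticFit, logistic_density
from .raster import GridSpec, effective_dims, init_tiles

__all__ = [
    "Gradient",
    "ColonySpec",
    "SynthSpec",
    "GroundTruth",
    "generate_plate",
    "generate_timecourse",
    "uniform_colonies",
]

#: Added peak intensity of a density-1.0 disc colony, in intensity units.
FULL_CONTRAST = 80.0
#: Slight yellow tint of culture pixels relative to the neutral agar.
CULTURE_TINT = (1.0, 1.0, 0.82)


@dataclass(frozen=True)
class Gradient:
    """Multiplicative lighting field: ``none``, ``linear`` or ``radial``.

    ``linear`` ramps the factor from ``min_factor`` to ``max_factor`` along
    ``direction`` ('x' or 'y'); ``radial`` falls from 1.0 at ``centre``
    (image centre when omitted) to ``min_factor`` at the farthest corner.
    """

    kind: str = "none"
    direction: str = "x"
    min_factor: float = 1.0
    max_factor: float = 1.0
    centre: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "radial"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        for f in (self.min_factor, self.max_factor):
            if not 0.5 <= f <= 1.5:
                raise ValueError("gradient factors must lie in [0.5, 1.5]")

    def field(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        if self.kind == "none":
            return np.ones((h, w))
        if self.kind == "linear":
            ramp = np.linspace(self.min_factor, self.max_factor, w if self.direction == "x" else h)
            return np.tile(ramp, (h, 1)) if self.direction == "x" else np.tile(ramp[:, None], (1, w))
        cy, cx = self.centre if self.centre is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.ogrid[:h, :w]
        r = np.hypot(yy - cy, xx - cx)
        corners = [np.hypot(y - cy, x - cx) for y in (0, h - 1) for x in (0, w - 1)]
        rmax = max(max(corners), 1.0)
        return 1.0 - (1.0 - self.min_factor) * (r / rmax)


@dataclass(frozen=True)
class ColonySpec:
    """One grid position's culture: presence, density, footprint, morphology."""

    present: bool = True
    density: float = 1.0  # in [0, 1]; 0 means absent from ground truth
    radius: float = 8.0  # pixels
    morphology: str = "disc"  # or "irregular-spot"
    edge_width: float | None = None  # boundary softness; None = radius/10, min 1 px

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.morphology not in ("disc", "irregular-spot"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.edge_width is not None and self.edge_width <= 0:
            raise ValueError("edge_width must be positive")


@dataclass(frozen=True)
class SynthSpec:
    """Full description of a synthetic plate; identical specs render identically."""

    grid: GridSpec
    colonies: tuple[ColonySpec, ...]  # row-major, one per grid position
    agar_level: float = 100.0
    gradient: Gradient = field(default_factory=Gradient)
    halo_amplitude: float = 0.0
    glare_walls: bool = False
    noise_sigma: float = 2.0
    contrast: float = FULL_CONTRAST
    seed: int = 0
    margin: float = 1.0  # image border, in tile units

    def __post_init__(self) -> None:
        n = self.grid.n_rows * self.grid.n_cols
        if len(self.colonies) != n:
            raise ValueError(f"expected {n} colony specs, got {len(self.colonies)}")

    def image_shape(self) -> tuple[int, int]:
        xd, yd = effective_dims(self.grid)
        w = int(round(self.grid.x_br + xd / 2 + self.margin * xd))
        h = int(round(self.grid.y_br + yd / 2 + self.margin * yd))
        return h, w


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-position truth for a rendered plate.

    ``label_map`` assigns each pixel its row-major position index (-1 for
    background), so truth masks are disjoint by construction.  ``true_iod``
    is the integrated added contrast of each colony profile (before
    gradient and noise).
    """

    label_map: np.ndarray  # int32, -1 = background
    true_area: np.ndarray  # int64 per position, row-major
    true_iod: np.ndarray  # float64 per position
    background: np.ndarray  # noiseless background field (agar * gradient)

    def mask(self, index: int) -> np.ndarray:
        return self.label_map == index


def uniform_colonies(
    grid: GridSpec,
    density: float = 1.0,
    radius: float = 8.0,
    morphology: str = "disc",
    present: bool = True,
    edge_width: float | None = None,
) -> tuple[ColonySpec, ...]:
    """Convenience: the same colony spec at every grid position."""
    n = grid.n_rows * grid.n_cols
    return tuple(
        ColonySpec(present=present, density=density, radius=radius,
                   morphology=morphology, edge_width=edge_width)
        for _ in range(n)
    )


def _disc_profile(radius: float, extent: int, rng: np.random.Generator,
                  edge_width: float | None = None) -> np.ndarray:
    """Near-binary disc with a narrow sigmoidal edge; peak height 1.

    Cultures keep a fairly defined footprint while their *opacity* varies
    with cell density, so density scales the profile height, not its edge
    softness.  The default edge width ``max(1, radius/10)`` suits spotted
    cultures; pinned colonies have harder boundaries (``edge_width ~ 0.5``).
    """
    yy, xx = np.mgrid[-extent:extent + 1, -extent:extent + 1].astype(np.float64)
    r = np.hypot(yy, xx)
    edge = max(1.0, radius / 10.0) if edge_width is None else edge_width
    return 1.0 / (1.0 + np.exp((r - radius) / edge))


def _irregular_profile(radius: float, extent: int, rng: np.random.Generator) -> np.ndarray:
    """Union of 5-30 jittered Gaussian sub-spots; normalised to peak 1."""
    yy, xx = np.mgrid[-extent:extent + 1, -extent:extent + 1].astype(np.float64)
    k = int(rng.integers(5, 31))
    prof = np.zeros_like(yy)
    for _ in range(k):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.7 * radius)
        cy, cx = rad * np.sin(ang), rad * np.cos(ang)
        s = rng.uniform(radius / 6.0, radius / 3.0)
        amp = rng.uniform(0.4, 1.0)
        prof += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s * s))
    peak = prof.max()
    return prof / peak if peak > 0 else prof


def generate_plate(s: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic plate photograph and its exact ground truth.

    Colony peak contrast is ``density * contrast`` and the truth mask is the
    set of pixels where the profile exceeds half its peak, so doubling
    density at a fixed footprint exactly doubles the true integrated
    density.  Colonies must stay within half a tile of their own tile
    boundary; anything larger is outside the tool's operating regime and
    raises.
    """
    xd, yd = effective_dims(s.grid)
    h, w = s.image_shape()
    rng = np.random.default_rng(s.seed)
    tiles = init_tiles(s.grid)

    base = np.full((h, w), float(s.agar_level))
    colony_field = np.zeros((h, w))
    halo_field = np.zeros((h, w))
    label_map = np.full((h, w), -1, dtype=np.int32)
    n_pos = len(tiles)
    true_area = np.zeros(n_pos, dtype=np.int64)
    true_iod = np.zeros(n_pos, dtype=np.float64)

    for idx, tile in enumerate(tiles):
        c = s.colonies[idx]
        if not (c.present and c.density > 0):
            continue
        if c.radius > min(xd, yd):
            raise ValueError(
                f"colony at ({tile.row},{tile.col}) radius {c.radius} overlaps "
                f"neighbouring tiles beyond half a tile"
            )
        cy = tile.y + tile.height / 2.0
        cx = tile.x + tile.width / 2.0
        extent = int(np.ceil(c.radius * 2.0))
        if c.morphology == "disc":
            prof = _disc_profile(c.radius, extent, rng, c.edge_width)
        else:
            prof = _irregular_profile(c.radius, extent, rng)
        peak = c.density * s.contrast
        prof = prof * peak

        y0 = int(round(cy)) - extent
        x0 = int(round(cx)) - extent
        ys = slice(max(y0, 0), min(y0 + prof.shape[0], h))
        xs = slice(max(x0, 0), min(x0 + prof.shape[1], w))
        pys = slice(ys.start - y0, ys.stop - y0)
        pxs = slice(xs.start - x0, xs.stop - x0)
        sub = prof[pys, pxs]
        colony_field[ys, xs] += sub

        in_mask = sub >= 0.5 * peak
        if (label_map[ys, xs][in_mask] != -1).any():
            raise ValueError("ground-truth colony masks overlap; shrink radii")
        region = label_map[ys, xs]
        region[in_mask] = idx
        label_map[ys, xs] = region
        true_area[idx] = int(in_mask.sum())
        true_iod[idx] = float(sub.sum())

        if s.halo_amplitude > 0:
            yy, xx = np.mgrid[ys, xs].astype(np.float64)
            r = np.hypot(yy - cy, xx - cx)
            ring = s.halo_amplitude * np.exp(
                -((r - 1.4 * c.radius) ** 2) / (2.0 * (c.radius / 3.0) ** 2)
            )
            halo_field[ys, xs] += np.where(r > c.radius, ring, 0.0)

    glare = np.zeros((h, w))
    if s.glare_walls:
        yy, xx = np.ogrid[:h, :w]
        d = np.minimum(np.minimum(yy, h - 1 - yy), np.minimum(xx, w - 1 - xx))
        glare = 40.0 * np.exp(-d / 8.0)

    grad = s.gradient.field((h, w))
    background = base * grad

    img = np.empty((h, w, 3))
    for ch in range(3):
        lum = base + colony_field * CULTURE_TINT[ch] + halo_field + glare
        img[..., ch] = lum * grad
    if s.noise_sigma > 0:
        img += rng.normal(0.0, s.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    truth = GroundTruth(
        label_map=label_map, true_area=true_area, true_iod=true_iod, background=background
    )
    return img, truth


def generate_timecourse(
    s: SynthSpec,
    fits: list[LogisticFit],
    times,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Render one plate per timepoint of a set of logistic growth curves.

    At time ``t`` each position's relative density is ``G(t)/K`` of its
    logistic curve.  Disc colonies keep their footprint and scale their
    amplitude, so their integrated added contrast is exactly proportional to
    ``G(t)/K`` and the rendered IOD is an unbiased surrogate for cell
    density (use discs for closed-loop growth-rate recovery).  Irregular
    spots additionally grow their footprint with density, emulating
    spreading dilute spots.  Frame seeds are derived deterministically from
    the spec seed.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.ndim != 1 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-D sequence")
    n_pos = len(s.colonies)
    if len(fits) != n_pos:
        raise ValueError("need one logistic fit per grid position")

    frames = []
    for fi, t in enumerate(times):
        cols = []
        for c, fit in zip(s.colonies, fits):
            if not c.present:
                cols.append(c)
                continue
            d = float(logistic_density(t, fit) / fit.k)
            d = float(np.clip(d, 0.0, 1.0))
            if c.morphology == "irregular-spot":
                cols.append(replace(c, density=d, radius=max(2.0, c.radius * (0.35 + 0.65 * d))))
            else:
                cols.append(replace(c, density=d))
        frame_seed = int((s.seed * 1009 + 31 * fi + 7) % (2**31 - 1))
        frame_spec = replace(s, colonies=tuple(cols), seed=frame_seed)
        frames.append(generate_plate(frame_spec))
    return frames
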