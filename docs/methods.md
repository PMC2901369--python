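# Methods

This note records the models, parameter choices and numerical conventions
behind `colonyquant`, and what the synthetic benchmark does and does not
establish about real plate photographs.

## Geometry and calibration

Images are 8-bit RGB rasters held as float64 in [0, 255]; greyscale
conversion uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114).  Pixel
coordinates are 0-based, `x` = column from the left, `y` = row from the
top; a tile is the half-open box `[x, x+w) × [y, y+h)`.

The user calibrates the grid once per batch (or per image) with the counts
`n_rows, n_cols` and the centres of the top-left and bottom-right cultures.
With more than one column the tile width is the corner-centre spacing
`(x_br − x_tl)/(n_cols − 1)`, so tiles exactly abut; a single-row or
single-column grid requires an explicit tile dimension.  The lattice starts
half a tile up-left of the top-left centre and steps one tile per grid
position.  Tile coordinates are rounded half-away-from-zero, once, at
construction; tiles keep their nominal size everywhere and are clamped to
the image only for pixel access.

## First-pass thresholding

The first pass only feeds the background reconstruction, so its loss
function is asymmetric: all culture signal must be captured, while agar
misclassified as culture costs nothing (it is refilled from its
neighbourhood).  Per tile:

* gradient mask: pixels strictly above the nearest-rank 95th percentile of
  the tile's Sobel gradient magnitudes (`keep_fraction = 0.05`);
* intensity cutoff: the nearest-rank 33rd percentile
  (`dark_fraction = 0.33`) of the masked pixels' intensities;
* culture: every tile pixel strictly brighter than the cutoff, so colony
  interiors survive along with their edges.

Both fractions are heuristics exposed in the configuration.  Percentiles
are nearest-rank on sorted values and "strictly above" resolves ties
toward background, so an all-equal tile yields no culture.  The Sobel
border policy is edge replication.  Note that on a signal-free (flat +
noise) tile the cutoff lands near the tile's own 33rd intensity percentile
— the Sobel magnitude at a pixel does not involve the pixel's own value —
so roughly two thirds of an empty tile is marked "culture".  This is by
design: those pixels are refilled faithfully during reconstruction, and
per-tile adaptivity is what lets the same fractions serve both blank and
fully-grown tiles.

## Pseudo-empty plate and lighting correction

The greyscale image is smoothed with a Gaussian of `σ = x_dim/4` (configurable)
— strong enough to suppress pixel noise at colony scale, gentle enough to
preserve plate-scale gradients.  First-pass culture pixels are cut out and
each gap refilled by linear interpolation along the scan line; each edge
value is the darkest pixel within `x_dim/2` (or `y_dim/2`) outside the gap,
which skips the bright halos that surround cultures via reflection through
the agar.  Horizontal and vertical fills, each from a fresh smoothed copy,
are merged by pointwise minimum so bright islands inside irregular
cultures cannot leak into the fill.  No re-smoothing is applied after
filling.  A fully-culture scan line (overgrown plates) falls back to the
plate-wide median of observed pixels; gaps touching the border take both
edge values from the single available side.

Correction ratios are `I_med / max(I_pe, 1)` with `I_med` the median
pseudo-empty intensity inside the grid bounding box; ratios are clipped to
[0.2, 5] and corrected intensities capped at 255, with both events logged
(the method assumes non-saturated source images and a multiplicative
lighting model — additive offsets are out of scope).  RGB channels share
the greyscale-derived ratio so colour measures stay comparable.

## Mixture segmentation

The corrected histogram over the grid box (bins 0..255; the saturated end
bins 0 and 255 are excluded from the fit) is modelled with two Gaussian
peaks parameterised by peak height: `g(x) = θ·N̄₁(x) + N̄₂(x)` with unit
peak heights and `θ` their ratio.  For the likelihood, `g` is normalised
over the fitted bins and `Σ counts[x]·log ĝ(x)` is maximised.  The global
search is a seeded differential evolution over `μ ∈ [1, 254]`,
`σ ∈ [0.5, 128]`, `log θ ∈ [log 10⁻⁴, log 10⁴]` with a local polish; a
method-of-moments start is also polished and the better optimum kept, so
the returned likelihood never falls below the moments initialisation.
Components are ordered `μ₁ < μ₂` post hoc (swapping inverts `θ`).  Fixed
seeds give bit-identical fits.

The threshold is the intersection of the components: equating them and
taking logs gives `a x² + b x + c = 0` with
`a = 1/2σ₂² − 1/2σ₁²`, `b = μ₁/σ₁² − μ₂/σ₂²`,
`c = μ₂²/2σ₂² − μ₁²/2σ₁² + ln θ`.  Of the real roots, the
highest-intensity one in `[μ₁, μ₂]` is used (else the highest real root;
nested components with no real intersection fall back to the midpoint with
a warning).  Pixels strictly above `x_thresh` are culture.

A blank plate has no second population, yet an unconstrained two-component
fit would split the single agar peak and threshold inside it.  The fit is
therefore compared against a single-Gaussian fit of the same histogram: if
twice the log-likelihood gain does not exceed the BIC penalty for the three
extra parameters (or the fitted means collapse within one bin), the plate
is flagged single-population and the mask is empty, with a "no growth
detected" warning.

## Tile refinement and measurements

Tile positions (sizes fixed) are refined by exhaustive search over offsets
`[-10, 9]²` (a 20×20 window, configurable), minimising the count of
culture pixels on the tile's one-pixel perimeter, implemented exactly via
a 2-D prefix sum.  Ties break toward the smallest Euclidean offset, then
row-major order, so an already-centred tile stays put.

Per refined tile: `area` is the culture-pixel count; `iod` is
`Σ max(I_corr − I_med, 0)` over culture pixels (the per-pixel clamp stops
bright agar contributing negative density); `tile_iod` is the same sum
over all tile pixels, clamped at zero as a whole; `granularity` counts
the tile's top-5%-gradient pixels (a texture measure); culture and agar
mean RGB come from the *uncorrected* image.  Edge tiles are measured but
flagged — edge cultures have a nutrient advantage and should be
non-experimental on dense formats.  Output is one tab-delimited row per
grid position, row-major, with `NA` for the colour of an empty culture.

## Logistic growth model

`G(t) = K·G₀·e^{rt} / (K + G₀·(e^{rt} − 1))`, evaluated in the stable form
`K / (1 + (K/G₀ − 1)e^{−rt})`.  Fitting is bounded least squares on the
linear density scale (log-scale residuals are a switch; linear is the
default), initialised from the data (`K` from the maximum, `G₀` from the
first positive point, `r` from the log-slope), with a few seeded restarts
on non-convergence.  All-zero series return a flagged no-growth fit; when
the optimiser lands on `G₀ = K` the curve is constant and `r` is
unidentifiable, so it is reported as 0.  Timecourses need at least four
observations at strictly increasing times.

## Synthetic plates

The generator renders
`image = (agar + Σ colony profiles + halos + glare) × gradient + noise`,
clipped to [0, 255], with a multiplicative lighting field (matching the
correction model), i.i.d. Gaussian pixel noise, an optional reflective
ring around each colony and exponential wall glare.  Defaults: agar level
100, full-density peak contrast 80, noise σ = 2 — typical of 8-bit plate
photographs.  Discs model a culture as a defined footprint whose *opacity*
scales with density: a sigmoid edge of width `max(1, radius/10)` for
spotted cultures, sharper (`edge_width ≈ 0.35–0.5`) for pinned colonies.
Irregular spots are unions of 5–30 seeded Gaussian sub-spots.  The ground
truth carries a disjoint label map (mask = profile above half its peak),
exact areas and the integrated added contrast, which for fixed-footprint
discs is exactly proportional to density.  Timecourse rendering drives
per-position densities through logistic curves; disc colonies keep their
footprint so rendered integrated contrast tracks `G(t)/K` linearly, which
is what makes closed-loop growth-rate recovery through the full pipeline
well-posed.  Identical specs (including the seed) render bit-identical
images.

What the generator does *not* emulate: agar cracks, contamination,
condensation, off-grid or streaked cultures, JPEG artefacts, and additive
(non-multiplicative) lighting.  Passing tests demonstrate correctness of
the algorithms under the stated image model, not performance on arbitrary
real photographs.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use compact study conditions
chosen to exercise every stage: 4×6 to 8×12 grids of 40 px tiles (plus one
16×24 blank-plate layout), faint-spot fixtures at peak contrast 8 with
noise σ = 2 under 0.8–1.2 linear gradients, 20 mixture histograms of
2×10⁵ samples spanning mixing fractions 0.5–0.99 and separations 2–10 σ,
and 12-frame growth series with `G₀/K = 0.05` and `r = 2–3.1`/day over
4 days — an inoculum and sampling schedule representative of spotted
timecourse experiments.

## Known limitations

* The equal-probability threshold sits near the noise floor by design, so
  segmented areas include a culture's faint skirt; for soft-edged spots
  the area exceeds the half-maximum footprint by 5–20% depending on
  contrast (IOD is the preferred density measure, and is insensitive to
  this).
* The darkest-pixel edge search biases the pseudo-empty plate slightly
  dark in proportion to the local lighting slope; under strong gradients
  this leaves a small residual spatial trend in corrected faint-colony
  areas.
* Correction assumes multiplicative lighting and non-saturated images;
  saturation and ratio clipping are logged, not repaired.
* Granularity counts high-gradient pixels over the whole tile, so it has
  a nonzero noise floor on empty tiles.
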