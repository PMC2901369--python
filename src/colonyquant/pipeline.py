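"""Batch orchestration of the full quantification pipeline.

Per image the stage order is fixed: load -> greyscale -> first-pass local
threshold -> pseudo-empty plate -> lighting correction (optional) ->
intensity histogram + mixture fit -> plate-wide mask -> tile refinement ->
measurements -> tab-delimited table.  Batches run in deterministic
(lexicographic) order, per-image failures are logged and skipped, and with
a fixed seed the whole pipeline is a pure function of the image bytes and
the configuration.
"""

from __future__ import annotations

import glob
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import background, firstpass, lighting, measure, mixture, raster

__all__ = ["PipelineConfig", "run_image", "run_batch"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to process a batch of plate images."""

    grid_config: str | Path | None = None  # path to the calibration file
    images: str | None = None  # input glob
    outdir: str | Path = "."
    lighting_correction: bool = True
    colour: bool = True
    diagnostics: bool = False
    keep_fraction: float = 0.05
    dark_fraction: float = 0.33
    smooth_sigma: float | None = None  # default: x_dim / 4
    search_halfwidth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must lie in (0, 1)")
        if not 0.0 < self.dark_fraction < 1.0:
            raise ValueError("dark_fraction must lie in (0, 1)")


def run_image(
    img: np.ndarray | str | Path,
    spec: raster.GridSpec,
    cfg: PipelineConfig | None = None,
    image_id: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full stage chain on one image.

    ``img`` may be a file path or an RGB raster.  Returns the measurement
    table and a diagnostics dict (mixture fit, median background, masks and
    quality flags).
    """
    cfg = cfg or PipelineConfig()
    if isinstance(img, (str, Path)):
        image_id = image_id or Path(img).name
        img = raster.load_image(img)
    else:
        img = np.asarray(img, dtype=np.float64)
        image_id = image_id or "image"
    grey = raster.to_greyscale(img)
    tiles = raster.init_tiles(spec)

    culture1, gmask, _gm = firstpass.firstpass_masks(
        grey, tiles, cfg.keep_fraction, cfg.dark_fraction
    )
    pe = background.build_pseudo_empty(grey, culture1, spec, sigma=cfg.smooth_sigma)
    i_med = lighting.median_background(pe, spec)
    if cfg.lighting_correction:
        cmap = lighting.build_correction(pe, i_med)
        corrected = lighting.apply_correction(grey, cmap)
    else:
        cmap = None
        corrected = grey

    no_growth = False
    try:
        hist = mixture.build_histogram(corrected, spec)
        fit = mixture.fit_mixture(hist, seed=cfg.seed)
        mask = mixture.segment_plate(corrected, fit)
        no_growth = fit.single_population
    except mixture.DegenerateHistogramError:
        log.warning("%s: degenerate intensity histogram; no growth detected", image_id)
        hist, fit = None, None
        mask = np.zeros(grey.shape, dtype=bool)
        no_growth = True

    measures = measure.quantify_plate(
        tiles, mask, corrected, img, gmask, i_med, spec,
        search=cfg.search_halfwidth, colour=cfg.colour,
    )
    frame = measure.measures_to_frame(measures, image_id)
    diagnostics = {
        "image_id": image_id,
        "fit": fit,
        "histogram": hist,
        "i_med": i_med,
        "no_growth": no_growth,
        "mask": mask,
        "pseudo_empty": pe,
        "correction": cmap,
        "corrected": corrected,
        "n_culture_pixels": int(mask.sum()),
    }
    if cfg.diagnostics:
        _dump_diagnostics(Path(cfg.outdir), image_id, diagnostics)
    return frame, diagnostics


def _dump_diagnostics(outdir: Path, image_id: str, diag: dict) -> None:
    """Optional PNG / plot dumps for visual inspection of each stage."""
    outdir.mkdir(parents=True, exist_ok=True)
    stem = Path(image_id).stem
    raster.save_image(outdir / f"{stem}.pseudo_empty.png", diag["pseudo_empty"].pixels)
    raster.save_image(outdir / f"{stem}.corrected.png", diag["corrected"])
    raster.save_image(outdir / f"{stem}.mask.png", diag["mask"].astype(float) * 255.0)
    if diag["fit"] is not None and diag["histogram"] is not None:
        _plot_histogram(outdir / f"{stem}.histogram.png", diag["histogram"], diag["fit"])


def _plot_histogram(path: Path, hist, fit) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, 255)
    counts = hist.fit_counts[1:255]
    g = mixture.mixture_density(x, fit.mu1, fit.sigma1, fit.mu2, fit.sigma2, fit.theta)
    scale = counts.sum() / max(g.sum(), 1e-12)
    c1 = fit.theta * np.exp(-((x - fit.mu1) ** 2) / (2 * fit.sigma1**2)) * scale
    c2 = np.exp(-((x - fit.mu2) ** 2) / (2 * fit.sigma2**2)) * scale
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(x, counts, "k+", ms=3, label="pixel counts")
    ax.plot(x, g * scale, "r-", label="mixture")
    ax.plot(x, c1, "b--", lw=0.8, label="components")
    ax.plot(x, c2, "b--", lw=0.8)
    ax.axvline(fit.x_thresh, color="g", label=f"threshold {fit.x_thresh:.1f}")
    ax.set_xlabel("intensity")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_batch(cfg: PipelineConfig) -> dict:
    """Process every image matching the configured glob, in sorted order.

    One ``<image>.dat`` table is written per input image.  Per-image
    failures are logged and skipped so a large batch always completes.
    Returns a summary dict with processed / failed counts and messages.
    """
    if not cfg.images:
        raise ValueError("no input image glob configured")
    paths = sorted(glob.glob(cfg.images))
    if not paths:
        raise FileNotFoundError(f"no images match {cfg.images!r}")
    if cfg.grid_config is None:
        raise ValueError("a grid calibration file is required")
    configs = raster.read_grid_config(cfg.grid_config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    processed, failed, failures = 0, 0, []
    for p in paths:
        try:
            spec = raster.grid_for_image(configs, p)
            frame, _diag = run_image(p, spec, cfg)
            measure.write_measures(frame, outdir / f"{Path(p).stem}.dat")
            processed += 1
        except Exception as exc:
            log.error("failed to process %s: %s", p, exc)
            failed += 1
            failures.append(f"{p}: {exc}")
    summary = {
        "processed": processed,
        "failed": failed,
        "failures": failures,
        "message": f"{processed} processed, {failed} failed",
    }
    log.info("batch complete: %s", summary["message"])
    return summary
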