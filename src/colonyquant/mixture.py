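"""Plate-wide segmentation with a two-component Gaussian mixture.

The histogram of corrected pixel intensities over the grid area is modelled
as the sum of two Gaussian peaks,

    g(x) = theta * exp(-(x - mu1)^2 / (2 sigma1^2))
               + exp(-(x - mu2)^2 / (2 sigma2^2)),

where ``theta`` is the ratio between the peak heights of the two components
(agar and culture).  Constraining the model to exactly two components
forces every pixel to be classified as one or the other.  The parameters
are estimated by maximising the log-likelihood of the binned intensities
under ``g`` normalised over the fitted bins, using a seeded
differential-evolution global search with a local polish.  The segmentation
threshold is the highest-intensity intersection of the two components —
the intensity at which a pixel is equally likely to belong to either — and
is available in closed form as the root of a quadratic.

Cultures at very low cell density are nearly as opaque as the agar, so
their intensity peak sits just beside (and far below) the agar peak; the
peak-height parameterisation with an unconstrained ratio ``theta`` is what
lets the fit latch onto such barely-visible signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .raster import GridSpec, grid_bbox

__all__ = [
    "IntensityHistogram",
    "MixtureFit",
    "DegenerateHistogramError",
    "build_histogram",
    "mixture_density",
    "fit_mixture",
    "solve_threshold",
    "segment_plate",
]

log = logging.getLogger(__name__)

_FIT_BINS = np.arange(1, 255)  # saturated bins 0 and 255 are trimmed
_BOUNDS = [(1.0, 254.0), (1.0, 254.0), (0.5, 128.0), (0.5, 128.0),
           (math.log(1e-4), math.log(1e4))]


class DegenerateHistogramError(ValueError):
    """Histogram occupies fewer than two bins; a mixture fit is meaningless."""


@dataclass(frozen=True)
class IntensityHistogram:
    """Integer-binned intensities over the grid area, bins 0..255.

    ``counts`` keeps the raw tallies for reporting; ``fit_counts`` has the
    saturated end bins (0 and 255) zeroed, and only those trimmed counts
    enter the likelihood.
    """

    counts: np.ndarray  # shape (256,), int64
    fit_counts: np.ndarray
    n_total: int

    @property
    def n_fit(self) -> int:
        return int(self.fit_counts.sum())


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-Gaussian mixture parameters and the derived threshold.

    ``mu1 < mu2`` by convention (the ordering is positional, not an agar /
    culture assignment).  ``single_population`` flags fits where a second
    component is not supported by the data (e.g. a blank plate): the
    two-component log-likelihood does not beat a single Gaussian by more
    than its BIC penalty, or the two means collapse onto one bin.
    """

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    theta: float
    loglik: float
    x_thresh: float
    single_population: bool = False
    loglik_single: float = float("nan")


def build_histogram(img: np.ndarray, spec: GridSpec) -> IntensityHistogram:
    """Histogram of (rounded) corrected intensities inside the grid bounding box."""
    ys, xs = grid_bbox(spec, img.shape)
    vals = np.clip(np.round(np.asarray(img, dtype=np.float64)[ys, xs]), 0, 255)
    counts = np.bincount(vals.astype(np.int64).ravel(), minlength=256)
    fit_counts = counts.copy()
    fit_counts[0] = 0
    fit_counts[255] = 0
    return IntensityHistogram(counts=counts, fit_counts=fit_counts, n_total=int(counts.sum()))


def mixture_density(x, mu1, sigma1, mu2, sigma2, theta):
    """Unnormalised mixture density ``g(x)`` (peak-height parameterisation)."""
    x = np.asarray(x, dtype=np.float64)
    return theta * np.exp(-((x - mu1) ** 2) / (2.0 * sigma1**2)) + np.exp(
        -((x - mu2) ** 2) / (2.0 * sigma2**2)
    )


def _neg_loglik(params: np.ndarray, fit_counts: np.ndarray) -> float:
    mu1, mu2, s1, s2, log_theta = params
    g = mixture_density(_FIT_BINS, mu1, s1, mu2, s2, math.exp(log_theta))
    z = g.sum()
    if not np.isfinite(z) or z <= 0:
        return 1e300
    occupied = fit_counts[1:255] > 0
    logp = np.log(np.maximum(g[occupied], 1e-300)) - math.log(z)
    return float(-(fit_counts[1:255][occupied] * logp).sum())


def _moment_init(fit_counts: np.ndarray) -> np.ndarray:
    """Method-of-moments starting point: split the histogram at its mean."""
    x = _FIT_BINS.astype(np.float64)
    c = fit_counts[1:255].astype(np.float64)
    n = c.sum()
    mean = (x * c).sum() / n
    lo = x <= mean
    out = []
    for part in (lo, ~lo):
        cp = c[part]
        xp = x[part]
        np_ = cp.sum()
        if np_ <= 0:
            out.append((mean, 4.0, 1.0))
            continue
        m = (xp * cp).sum() / np_
        v = ((xp - m) ** 2 * cp).sum() / np_
        out.append((m, max(math.sqrt(v), 0.5), np_))
    (m1, s1, n1), (m2, s2, n2) = out
    # theta from implied peak heights (weight / sigma)
    theta = (n1 / s1) / max(n2 / s2, 1e-12)
    theta = min(max(theta, 1e-4), 1e4)
    return np.array([m1, m2, s1, s2, math.log(theta)])


def _fit_single_gaussian(fit_counts: np.ndarray) -> float:
    """Max log-likelihood of a single Gaussian over the same trimmed bins."""
    x = _FIT_BINS.astype(np.float64)
    c = fit_counts[1:255].astype(np.float64)
    n = c.sum()
    mean = (x * c).sum() / n
    sd = max(math.sqrt(((x - mean) ** 2 * c).sum() / n), 0.25)

    def nll(p):
        mu, sigma = p
        g = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
        z = g.sum()
        if z <= 0 or not np.isfinite(z):
            return 1e300
        occ = c > 0
        return float(-(c[occ] * (np.log(np.maximum(g[occ], 1e-300)) - math.log(z))).sum())

    res = optimize.minimize(
        nll, [mean, sd], method="L-BFGS-B", bounds=[(1.0, 254.0), (0.25, 200.0)]
    )
    return float(-res.fun)


def _ordered(params: np.ndarray) -> tuple[float, float, float, float, float]:
    """Enforce mu1 < mu2; swapping components inverts the peak-height ratio."""
    mu1, mu2, s1, s2, log_theta = params
    theta = math.exp(log_theta)
    if mu1 <= mu2:
        return mu1, s1, mu2, s2, theta
    return mu2, s2, mu1, s1, 1.0 / theta


def fit_mixture(hist: IntensityHistogram, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood fit of the two-Gaussian mixture to a histogram.

    A seeded bounded differential-evolution search (replacing the original
    genetic optimiser) explores mu in [1, 254], sigma in [0.5, 128] and
    theta in [1e-4, 1e4] (log-parameterised); its best candidate and a
    method-of-moments start are both polished locally and the better result
    is kept, so the returned likelihood never falls below the moments
    initialisation.  Identical seeds give bit-identical fits.
    """
    if np.count_nonzero(hist.fit_counts) < 2:
        raise DegenerateHistogramError(
            "histogram occupies fewer than two intensity bins; no mixture to fit"
        )
    fc = hist.fit_counts

    de = optimize.differential_evolution(
        _neg_loglik,
        _BOUNDS,
        args=(fc,),
        seed=seed,
        maxiter=250,
        tol=1e-10,
        polish=True,
        updating="deferred",
    )
    candidates = [de.x]
    mom = _moment_init(fc)
    local = optimize.minimize(
        _neg_loglik, mom, args=(fc,), method="L-BFGS-B", bounds=_BOUNDS
    )
    candidates.append(local.x)
    best = min(candidates, key=lambda p: _neg_loglik(p, fc))
    loglik = -_neg_loglik(best, fc)

    mu1, s1, mu2, s2, theta = _ordered(best)
    loglik_single = _fit_single_gaussian(fc)
    n_fit = hist.n_fit
    # BIC comparison: the mixture has 3 more parameters than one Gaussian.
    bic_margin = 2.0 * (loglik - loglik_single) - 3.0 * math.log(max(n_fit, 2))
    single = bool(bic_margin <= 0.0 or (mu2 - mu1) < 1.0)

    fit = MixtureFit(
        mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2, theta=theta,
        loglik=loglik, x_thresh=0.0,
        single_population=single, loglik_single=loglik_single,
    )
    return MixtureFit(**{**fit.__dict__, "x_thresh": solve_threshold(fit)})


def solve_threshold(fit: MixtureFit) -> float:
    """Intensity at which the two component curves intersect.

    Equating the components and taking logs gives a quadratic in ``x``; of
    its real roots the highest-intensity one lying in ``[mu1, mu2]`` is
    returned (else the highest real root).  When the components are nested
    with no real intersection the midpoint ``(mu1 + mu2)/2`` is used with a
    warning.  The result is clipped to [0, 255].
    """
    s1sq, s2sq = fit.sigma1**2, fit.sigma2**2
    a = 1.0 / (2.0 * s2sq) - 1.0 / (2.0 * s1sq)
    b = fit.mu1 / s1sq - fit.mu2 / s2sq
    c = fit.mu2**2 / (2.0 * s2sq) - fit.mu1**2 / (2.0 * s1sq) + math.log(fit.theta)

    roots: list[float]
    if abs(a) < 1e-12:
        roots = [] if abs(b) < 1e-12 else [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    if not roots:
        log.warning("mixture components do not intersect; falling back to the midpoint")
        x = (fit.mu1 + fit.mu2) / 2.0
    else:
        inside = [r for r in roots if fit.mu1 <= r <= fit.mu2]
        x = max(inside) if inside else max(roots)
    return float(min(max(x, 0.0), 255.0))


def segment_plate(img: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Plate-wide culture mask: pixel is culture iff intensity > x_thresh.

    A single-population fit (blank plate) yields an all-background mask and
    logs a "no growth detected" flag.
    """
    img = np.asarray(img, dtype=np.float64)
    if fit.single_population:
        log.warning("no growth detected: single-population intensity fit; mask is empty")
        return np.zeros(img.shape, dtype=bool)
    return img > fit.x_thresh
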