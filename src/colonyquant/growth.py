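"""Logistic growth-curve fitting for culture density timecourses.

Cell density observations (IOD or area) captured at several times after
inoculation are summarised with the logistic population model

    G(t) = K * G0 * exp(r t) / (K + G0 * (exp(r t) - 1)),

with ``G0 = G(0)`` the inoculum density, ``K`` the carrying capacity (the
maximum achievable density for that culture) and ``r`` the growth rate per
day.  The exponential-phase growth rate ``r`` is usually the phenotype of
interest: unlike final density it is insensitive to competition for
nutrients and to small variations in inoculum concentration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["LogisticFit", "logistic_density", "fit_logistic", "fit_growth_tables"]

_EPS = 1e-6
_R_MAX = 100.0  # per day; generous bound for microbial cultures


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters for one culture's timecourse."""

    g0: float
    k: float
    r: float
    rss: float
    converged: bool
    no_growth: bool = False


def logistic_density(t, fit: LogisticFit | None = None, *, g0=None, k=None, r=None):
    """Closed-form logistic solution ``G(t)``; accepts a fit or raw parameters.

    Evaluated in the numerically stable form ``K / (1 + (K/G0 - 1) e^{-rt})``
    so large ``r t`` cannot overflow.
    """
    if fit is not None:
        g0, k, r = fit.g0, fit.k, fit.r
    t = np.asarray(t, dtype=np.float64)
    if g0 <= 0 or k <= 0:
        raise ValueError("g0 and k must be positive")
    out = k / (1.0 + (k / g0 - 1.0) * np.exp(-r * t))
    return out if out.ndim else float(out)


def _residuals(params, times, dens, log_scale):
    g0, k, r = params
    model = k / (1.0 + (k / g0 - 1.0) * np.exp(-r * times))
    if log_scale:
        return np.log(model + _EPS) - np.log(dens + _EPS)
    return model - dens


def fit_logistic(
    times,
    densities,
    seed: int = 0,
    log_scale: bool = False,
) -> LogisticFit:
    """Least-squares fit of ``(G0, K, r)`` to a density timecourse.

    Residuals are taken on the linear density scale by default
    (``log_scale=True`` switches to log residuals).  Initialisation: ``K``
    from the maximum density, ``G0`` from the first positive observation and
    ``r`` from the log-slope between the first positive point and the
    maximum; the bounded trust-region fit is retried from a few seeded
    perturbations if it fails to converge.  An all-zero series is returned
    as a flagged no-growth fit.
    """
    times = np.asarray(times, dtype=np.float64)
    dens = np.asarray(densities, dtype=np.float64)
    if times.shape != dens.shape or times.ndim != 1:
        raise ValueError("times and densities must be 1-D arrays of equal length")
    if times.size < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if np.any(dens < 0):
        raise ValueError("densities must be nonnegative")

    if not np.any(dens > 0):
        return LogisticFit(g0=_EPS, k=_EPS, r=0.0, rss=0.0, converged=True, no_growth=True)

    k0 = float(dens.max())
    pos = np.flatnonzero(dens > 0)
    g00 = float(min(dens[pos[0]], k0))
    i_max = int(np.argmax(dens))
    if i_max > pos[0] and dens[i_max] > dens[pos[0]]:
        r0 = float(
            np.log(dens[i_max] / dens[pos[0]]) / max(times[i_max] - times[pos[0]], 1e-9)
        )
    else:
        r0 = 0.1
    r0 = float(np.clip(r0, 1e-3, _R_MAX))

    lower = [_EPS, _EPS, 0.0]
    upper = [np.inf, np.inf, _R_MAX]
    starts = [np.array([g00, max(k0, g00), r0])]
    rng = np.random.default_rng(seed)
    for _ in range(3):
        jitter = rng.uniform(0.3, 3.0, size=3)
        starts.append(np.array([g00 * jitter[0], max(k0 * jitter[1], _EPS), r0 * jitter[2]]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = optimize.least_squares(
                _residuals, x0, args=(times, dens, log_scale),
                bounds=(lower, upper), method="trf", x_scale=np.maximum(x0, _EPS),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.success and best.cost < 1e-20:
            break
    if best is None:
        return LogisticFit(g0=g00, k=k0, r=r0, rss=float("inf"), converged=False)

    g0, k, r = best.x
    g0 = min(g0, k)  # enforce the inoculum <= carrying capacity invariant
    if k - g0 < 1e-6 * k:
        r = 0.0  # g0 == k: the curve is constant and the rate unidentifiable
    rss = float(np.sum(_residuals([g0, k, r], times, dens, log_scale) ** 2))
    return LogisticFit(g0=float(g0), k=float(k), r=float(r), rss=rss,
                       converged=bool(best.success))


def fit_growth_tables(
    table_paths,
    time_regex: str,
    density_col: str = "iod",
    seed: int = 0,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Fit the logistic model to every culture across a set of plate tables.

    ``table_paths`` are tab-delimited per-image measurement tables from the
    quantification pipeline; the observation time (in days) is parsed from
    each file name with ``time_regex``, whose first capture group must be a
    number.  Tables are joined on ``(row, col)`` and the chosen density
    column fitted per culture.  Returns a frame with columns
    ``row, col, g0, k, r, rss, converged``.
    """
    pattern = re.compile(time_regex)
    frames = []
    for p in sorted(str(p) for p in table_paths):
        m = pattern.search(Path(p).name)
        if m is None:
            raise ValueError(f"time pattern {time_regex!r} does not match file name {p!r}")
        t = float(m.group(1))
        df = pd.read_csv(p, sep="\t")
        df["time"] = t
        frames.append(df)
    if not frames:
        raise ValueError("no measurement tables supplied")
    allobs = pd.concat(frames, ignore_index=True)
    if density_col not in allobs.columns:
        raise ValueError(f"density column {density_col!r} not present in tables")

    rows = []
    for (row, col), grp in allobs.groupby(["row", "col"], sort=True):
        grp = grp.sort_values("time")
        fit = fit_logistic(
            grp["time"].to_numpy(), grp[density_col].to_numpy(),
            seed=seed, log_scale=log_scale,
        )
        rows.append({
            "row": row, "col": col, "g0": fit.g0, "k": fit.k, "r": fit.r,
            "rss": fit.rss, "converged": int(fit.converged),
        })
    return pd.DataFrame(rows, columns=["row", "col", "g0", "k", "r", "rss", "converged"])
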