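"""Circular kernel estimate of the daily activity cycle.

The activity level is the proportion of the day the population is active,
estimated as 1 / (2*pi * peak) of a von Mises kernel density fitted to
event times expressed as radians on the 24 h circle.  Uncertainty comes
from a nonparametric bootstrap over events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "ActivityEstimate",
    "bootstrap_activity",
    "fit_activity",
    "times_to_radians",
    "vonmises_kde",
]

_GRID_N = 512
SECONDS_PER_DAY = 86400.0


@dataclass
class ActivityEstimate:
    level: float
    se: float | None
    n_events: int
    bandwidth: float  # von Mises kernel concentration
    grid: np.ndarray
    density: np.ndarray


def times_to_radians(seconds_into_day: np.ndarray) -> np.ndarray:
    """Clock time (seconds into the day, any epoch at midnight) -> [0, 2pi)."""
    s = np.asarray(seconds_into_day, dtype=float) % SECONDS_PER_DAY
    return 2.0 * np.pi * s / SECONDS_PER_DAY


def _kappa_ml(radians: np.ndarray) -> float:
    """Von Mises concentration from mean resultant length (standard approx)."""
    c = np.cos(radians).mean()
    s = np.sin(radians).mean()
    r = math.hypot(c, s)
    if r < 1e-8:
        return 1e-6
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    r = min(r, 0.999)  # cap: degenerate samples would send kappa to infinity
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def _kappa_from_moments(radians: np.ndarray, max_order: int = 3) -> float:
    """Concentration matching trigonometric moments of order 1..max_order.

    Higher orders keep the estimate informative for multimodal samples
    (antipodal modes cancel the first-order resultant).
    """
    from scipy.optimize import brentq

    best = _kappa_ml(radians)
    # Rayleigh-test cutoff: a higher-order moment indistinguishable from
    # uniform noise must not set the bandwidth
    rho_crit = math.sqrt(4.6 / len(radians))
    for k in range(2, max_order + 1):
        c = np.cos(k * radians).mean()
        s = np.sin(k * radians).mean()
        rho = math.hypot(c, s)
        if rho < rho_crit or rho >= 1 - 1e-9:
            continue

        def f(kap, k=k, rho=rho):
            return special.ive(k, kap) / special.ive(0, kap) - rho

        if f(1e-6) < 0 < f(1000.0):
            best = max(best, brentq(f, 1e-6, 1000.0, xtol=1e-8))
    return best


def bandwidth_kappa(radians: np.ndarray) -> float:
    """Rule-of-thumb kernel concentration for von Mises KDE (Taylor-type)."""
    n = len(radians)
    k = _kappa_from_moments(radians)
    # exponentially-scaled Bessels: the e^{2k} factors cancel exactly
    num = 3.0 * n * k**2 * special.ive(2, 2 * k)
    den = 4.0 * math.sqrt(math.pi) * special.ive(0, k) ** 2
    if num <= 0 or den <= 0:
        return 1e-6
    return float((num / den) ** 0.4)


def vonmises_kde(radians: np.ndarray, kappa: float, grid: np.ndarray) -> np.ndarray:
    """Von Mises kernel density of events, evaluated on ``grid``."""
    radians = np.asarray(radians, dtype=float)
    if kappa < 1e-6:
        return np.full(len(grid), 1.0 / (2 * np.pi))
    # chunk to bound the (n x grid) matrix
    out = np.zeros(len(grid))
    norm = 1.0 / (2 * np.pi * special.i0e(kappa) * len(radians))
    for start in range(0, len(radians), 4096):
        chunk = radians[start : start + 4096]
        out += np.exp(kappa * (np.cos(grid[:, None] - chunk[None, :]) - 1.0)).sum(axis=1)
    return out * norm


def fit_activity(
    event_radians: np.ndarray,
    bandwidth_adjust: float = 1.5,
    bandwidth: float | None = None,
    refine: bool = True,
) -> ActivityEstimate:
    """Fit the activity kernel and return the activity level (no SE yet).

    The kernel concentration is the rule-of-thumb value multiplied by
    ``bandwidth_adjust`` unless an explicit ``bandwidth`` is given.
    """
    x = np.asarray(event_radians, dtype=float) % (2 * np.pi)
    if len(x) < 10:
        raise ValueError("need at least 10 events")
    if np.ptp(x) < 1e-12:
        warnings.warn("all events identical; activity level is degenerate")
    kappa = bandwidth if bandwidth is not None else bandwidth_adjust * bandwidth_kappa(x)
    grid = np.linspace(0.0, 2 * np.pi, _GRID_N, endpoint=False)
    dens = vonmises_kde(x, kappa, grid)
    i = int(np.argmax(dens))
    peak = float(dens[i])
    if refine and kappa >= 1e-6:
        lo, hi = grid[i] - 2 * np.pi / _GRID_N, grid[i] + 2 * np.pi / _GRID_N
        res = optimize.minimize_scalar(
            lambda t: -float(vonmises_kde(x, kappa, np.array([t]))[0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        peak = max(peak, -float(res.fun))
    level = min(1.0, 1.0 / (2 * np.pi * peak))
    return ActivityEstimate(
        level=level, se=None, n_events=len(x), bandwidth=kappa, grid=grid, density=dens
    )


def bootstrap_activity(
    event_radians: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    bandwidth_adjust: float = 1.5,
) -> ActivityEstimate:
    """Activity level with a bootstrap SE (B resamples with replacement)."""
    if B < 2:
        raise ValueError("B must be >= 2")
    x = np.asarray(event_radians, dtype=float) % (2 * np.pi)
    est = fit_activity(x, bandwidth_adjust=bandwidth_adjust)
    rng = np.random.default_rng(seed)
    levels = np.empty(B)
    for b in range(B):
        xb = rng.choice(x, size=len(x), replace=True)
        levels[b] = fit_activity(xb, bandwidth_adjust=bandwidth_adjust, refine=False).level
    est.se = float(np.std(levels, ddof=1))
    return est
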