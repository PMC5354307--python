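"""Headless (axial) angle statistics.

Fibre orientations carry no arrow: an angle theta and theta + 180 deg denote
the same direction, so planar orientations live on a half-circle [0, 180).
All helpers here operate on that axial convention, with distances measured as

    d(a, b) = min(|a - b| mod 180, 180 - |a - b| mod 180)   (degrees).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "axial_distance",
    "circular_mean",
    "circular_median",
    "circular_iqr",
    "axial_variance",
]


def axial_distance(a, b):
    """Headless angular distance in degrees, in [0, 90]."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 180.0
    return np.minimum(d, 180.0 - d)


def circular_mean(thetas) -> float:
    """Headless circular mean via the doubled-angle resultant, in [0, 180)."""
    th = np.deg2rad(np.asarray(thetas, dtype=float) * 2.0)
    s, c = np.sin(th).mean(), np.cos(th).mean()
    return float(np.rad2deg(np.arctan2(s, c)) / 2.0 % 180.0)


def circular_median(thetas) -> float:
    """Headless circular median.

    The angle minimizing sum_i d(theta, theta_i).  The objective is piecewise
    linear with breakpoints at the data angles and their perpendiculars, so it
    suffices to evaluate those candidates.  Ties break to the smallest angle.
    """
    th = np.asarray(thetas, dtype=float) % 180.0
    if th.size == 0:
        raise ValueError("empty angle set")
    cand = np.unique(np.concatenate([th, (th + 90.0) % 180.0]))
    cost = axial_distance(cand[:, None], th[None, :]).sum(axis=1)
    best = cost.min()
    return float(cand[cost <= best + 1e-9].min())


def circular_iqr(thetas) -> float:
    """Headless interquartile range in degrees.

    The data are rotated so the circular median maps to 90 deg, then the
    ordinary IQR of the rotated angles is taken.
    """
    th = np.asarray(thetas, dtype=float)
    med = circular_median(th)
    rot = (th - med + 90.0) % 180.0
    q75, q25 = np.percentile(rot, [75, 25])
    return float(q75 - q25)


_VAR_GRID = np.arange(0.0, 180.0, 1.0)
_VAR_D2 = ((((_VAR_GRID[:, None] + 0.5) - _VAR_GRID[None, :] + 90.0) % 180.0) - 90.0) ** 2


def axial_variance(thetas) -> float:
    """Headless (Frechet) variance in deg^2: min_mu mean_i d(theta_i, mu)^2.

    A histogram grid (1-deg bins) locates the minimizing direction; a few
    fixed-point refinements on the exact data (the assignment of points to
    the half-circle around mu is then fixed, making the objective quadratic)
    give the optimum.
    """
    th = np.asarray(thetas, dtype=float) % 180.0
    if th.size == 0:
        return 0.0
    hist = np.bincount(th.astype(np.int64) % 180, minlength=180).astype(float)
    cost = _VAR_D2 @ hist
    mu = _VAR_GRID[int(np.argmin(cost))]
    for _ in range(3):
        d0 = ((th - mu + 90.0) % 180.0) - 90.0
        mu = mu + d0.mean()
    d = ((th - mu + 90.0) % 180.0) - 90.0
    return float((d**2).mean())
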