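"""Phases IX-X and verification statistics: smoothing, bundle widths,
equivalence tests.

Final smoothing removes edge / vessel / placenta points, multiplies the
direction field by its weight and convolves with a radius-1 Gaussian whose
stencil *excludes* edge points, so boundaries between bundles never bleed.
Vectors are headless, so each stencil contribution is sign-aligned to the
centre vector before averaging; output directions are the normalized sums,
output weights their lengths (renormalized over the included stencil mass).

Bundle widths are sampled on a randomly offset lattice (4 voxels in-plane,
1 in z; 4 regions in 2D): at each tissue point a line perpendicular to the
local fibre direction (drawn uniformly from the perpendicular great circle
in 3D) is stepped in 0.5-voxel increments in both senses until it leaves the
tissue; the distance between the stop points is the width.

Registered and unregistered width distributions are compared by (a) a
normal-theory (Welch) 95% CI of the difference of log-mean widths against
the 5% equivalence interval (log 0.95, log 1.05) = (-0.0488, 0.0513), and
(b) a bootstrap Kolmogorov-Smirnov test: repeated 1000-value subsamples give
the distribution of the normalized statistic sqrt(nm/(n+m)) D, whose 90% CI
must lie below the critical value c(0.05) = 1.36.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import WidthParams
from .regions import CAT_PLANAR

__all__ = ["final_smooth", "smooth_slide_2d", "measure_widths_2d",
           "measure_widths_3d", "equivalence_stats", "width_maps",
           "EquivalenceReport"]

_OFFSETS3 = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
             for dx in (-1, 0, 1)]


def _shift(arr: np.ndarray, off: tuple) -> np.ndarray:
    """Zero-padded shift of arr by +off (off in index space)."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for o, n in zip(off, arr.shape):
        src.append(slice(max(-o, 0), n - max(o, 0)))
        dst.append(slice(max(o, 0), n + min(o, 0)))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def final_smooth(vec: np.ndarray, weight: np.ndarray,
                 exclude: np.ndarray, sigma: float = 1.0) -> tuple:
    """Radius-1 Gaussian smoothing of the weighted headless field.

    ``exclude`` points (edges, vessels, placenta) are removed and excluded
    from every stencil.  Returns (directions, weights).
    """
    g1 = np.exp(-0.5 * (np.arange(-1, 2) / sigma) ** 2)
    w2 = np.where(exclude, 0.0, weight)
    vw = vec * w2[..., None]
    incl = (~exclude).astype(np.float64)
    num = np.zeros_like(vw)
    mass = np.zeros_like(w2)
    for off in _OFFSETS3:
        gk = g1[off[0] + 1] * g1[off[1] + 1] * g1[off[2] + 1]
        sv = np.stack([_shift(vw[..., c], tuple(-o for o in off))
                       for c in range(3)], axis=-1)
        si = _shift(incl, tuple(-o for o in off))
        sign = np.sign((sv * vec).sum(-1))
        sign[sign == 0] = 1.0
        num += gk * sv * sign[..., None] * si[..., None]
        mass += gk * si
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.where(mass[..., None] > 0, num / mass[..., None], 0.0)
    out_w = np.sqrt((num**2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out_v = np.where(out_w[..., None] > 1e-12, num / out_w[..., None], 0.0)
    out_w = np.where(exclude, 0.0, out_w)
    out_v = np.where(exclude[..., None], 0.0, out_v)
    return out_v, out_w


def smooth_slide_2d(category: np.ndarray, theta: np.ndarray,
                    exclude: np.ndarray, sigma: float = 1.0) -> tuple:
    """Radius-1 double-angle smoothing of a slide's planar directions.

    Returns (planar mask, smoothed theta): planar pixels not excluded keep a
    direction given by the edge-respecting Gaussian average of their
    neighbours' doubled angles.
    """
    pl = (category == CAT_PLANAR) & ~exclude
    t2 = np.deg2rad(np.nan_to_num(theta) * 2.0)
    cx = np.where(pl, np.cos(t2), 0.0)
    sx = np.where(pl, np.sin(t2), 0.0)
    g1 = np.exp(-0.5 * (np.arange(-1, 2) / sigma) ** 2)
    nc = np.zeros_like(cx)
    ns = np.zeros_like(sx)
    mass = np.zeros_like(cx)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            gk = g1[dy + 1] * g1[dx + 1]
            nc += gk * _shift(cx, (-dy, -dx))
            ns += gk * _shift(sx, (-dy, -dx))
            mass += gk * _shift(pl.astype(float), (-dy, -dx))
    th = (np.rad2deg(np.arctan2(ns, nc)) / 2.0) % 180.0
    return pl, np.where(pl, th, np.nan)


def _trace_width(tissue_test, origin: np.ndarray, direction: np.ndarray,
                 step: float, max_steps: int) -> float:
    """Distance between the first failing sample points in both senses."""
    lo = hi = 0
    for k in range(1, max_steps + 1):
        if not tissue_test(origin + k * step * direction):
            hi = k
            break
    else:
        hi = max_steps
    for k in range(1, max_steps + 1):
        if not tissue_test(origin - k * step * direction):
            lo = k
            break
    else:
        lo = max_steps
    return (lo + hi) * step


def measure_widths_2d(planar: np.ndarray, theta: np.ndarray, pitch_um: float,
                      params: WidthParams | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Width samples on one slide: perpendicular to theta, within planar tissue."""
    params = params or WidthParams()
    rng = rng or np.random.default_rng(0)
    h, w = planar.shape
    gy, gx = rng.uniform(0, params.grid_regions, 2)
    ys = np.arange(int(np.ceil(gy)), h, params.grid_regions, dtype=int) \
        if gy else np.arange(0, h, params.grid_regions, dtype=int)
    xs = np.arange(int(np.ceil(gx)), w, params.grid_regions, dtype=int) \
        if gx else np.arange(0, w, params.grid_regions, dtype=int)
    max_steps = int(2 * max(h, w) / params.step_voxels)

    def tissue(p):
        x, y = int(np.rint(p[0])), int(np.rint(p[1]))
        return 0 <= x < w and 0 <= y < h and planar[y, x]

    rows = []
    for y in ys:
        for x in xs:
            if not planar[y, x]:
                continue
            perp = np.deg2rad(theta[y, x] + 90.0)
            u = np.array([np.cos(perp), np.sin(perp)])
            width = _trace_width(tissue, np.array([x, y], float), u,
                                 params.step_voxels, max_steps)
            rows.append((x, y, u[0], u[1], width * pitch_um))
    if not rows:
        raise ValueError("no samples")
    return pd.DataFrame(rows, columns=["x", "y", "ux", "uy", "width_um"])


def measure_widths_3d(vec: np.ndarray, weight: np.ndarray, pitch_um: float,
                      params: WidthParams | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Width samples in the volume, perpendicular (random azimuth) to the field."""
    params = params or WidthParams()
    rng = rng or np.random.default_rng(0)
    nz, ny, nx = weight.shape
    offs = rng.uniform(0, params.grid_regions, 2)
    offz = rng.uniform(0, params.grid_z)
    zs = np.arange(int(np.ceil(offz)), nz, params.grid_z, dtype=int)
    ys = np.arange(int(np.ceil(offs[0])), ny, params.grid_regions, dtype=int)
    xs = np.arange(int(np.ceil(offs[1])), nx, params.grid_regions, dtype=int)
    tissue_mask = weight > params.weight_threshold
    max_steps = int(2 * max(nz, ny, nx) / params.step_voxels)

    def tissue(p):
        x, y, z = (int(np.rint(v)) for v in p)
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz \
            and tissue_mask[z, y, x]

    rows = []
    for z in zs:
        for y in ys:
            for x in xs:
                if not tissue_mask[z, y, x]:
                    continue
                v = vec[z, y, x]
                n = np.linalg.norm(v)
                if n < 1e-9:
                    continue
                v = v / n
                a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 \
                    else np.array([0.0, 1.0, 0.0])
                e1 = np.cross(v, a)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(v, e1)
                psi = rng.uniform(0, 2 * np.pi)
                u = np.cos(psi) * e1 + np.sin(psi) * e2
                width = _trace_width(tissue, np.array([x, y, z], float), u,
                                     params.step_voxels, max_steps)
                rows.append((x, y, z, u[0], u[1], u[2], width * pitch_um))
    if not rows:
        raise ValueError("no samples")
    return pd.DataFrame(rows, columns=["x", "y", "z", "ux", "uy", "uz",
                                       "width_um"])


@dataclass
class EquivalenceReport:
    mean_log_diff: float
    ci95: tuple
    effect_interval: tuple
    mean_equivalent: bool
    ks_stat_full: float
    ks_prob: float              # P(normalized D_1000,1000 < c)
    ks_ci90: tuple
    ks_equivalent: bool
    verdict: str                # 'equivalent' | 'not_equivalent'
    n_u: int
    n_r: int


def equivalence_stats(widths_u, widths_r, params: WidthParams | None = None,
                      rng: np.random.Generator | None = None
                      ) -> EquivalenceReport:
    """Equivalence of unregistered vs registered width distributions.

    Mean: Welch 95% CI of the difference of log means must sit inside the 5%
    effect interval.  Distribution: bootstrap CI of the normalized
    Kolmogorov-Smirnov statistic must lie below c(0.05) = 1.36.
    """
    params = params or WidthParams()
    rng = rng or np.random.default_rng(0)
    wu = np.asarray(widths_u, dtype=float)
    wr = np.asarray(widths_r, dtype=float)
    if len(wu) < params.ks_sample or len(wr) < params.ks_sample:
        raise ValueError(f"need at least {params.ks_sample} values per sample")
    lu, lr = np.log(wu), np.log(wr)
    diff = lu.mean() - lr.mean()
    se = np.sqrt(lu.var(ddof=1) / len(lu) + lr.var(ddof=1) / len(lr))
    dof = se**4 / ((lu.var(ddof=1) / len(lu))**2 / (len(lu) - 1)
                   + (lr.var(ddof=1) / len(lr))**2 / (len(lr) - 1))
    tcrit = stats.t.ppf(0.975, dof)
    ci = (diff - tcrit * se, diff + tcrit * se)
    lo, hi = params.effect_interval
    mean_ok = lo < ci[0] and ci[1] < hi
    n, m = len(wu), len(wr)
    d_full = stats.ks_2samp(wu, wr, method="asymp").statistic
    k_full = float(np.sqrt(n * m / (n + m)) * d_full)
    k = params.ks_sample
    norm = np.sqrt(k * k / (2 * k))
    ks = np.empty(params.ks_reps)
    for i in range(params.ks_reps):
        su = rng.choice(wu, size=k, replace=len(wu) < 2 * k)
        sr = rng.choice(wr, size=k, replace=len(wr) < 2 * k)
        ks[i] = norm * stats.ks_2samp(su, sr, method="asymp").statistic
    alpha = (1.0 - params.ks_ci) / 2.0
    ci90 = tuple(np.quantile(ks, [alpha, 1.0 - alpha]))
    ks_ok = ci90[1] < params.ks_critical
    prob = float((ks < params.ks_critical).mean())
    verdict = "equivalent" if (mean_ok and ks_ok) else "not_equivalent"
    return EquivalenceReport(mean_log_diff=float(diff), ci95=ci,
                             effect_interval=(lo, hi), mean_equivalent=mean_ok,
                             ks_stat_full=k_full, ks_prob=prob, ks_ci90=ci90,
                             ks_equivalent=ks_ok, verdict=verdict,
                             n_u=n, n_r=m)


def _median_ci(x: np.ndarray) -> tuple:
    """Binomial order-statistic 95% CI of the median."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n == 0:
        return (np.nan, np.nan, np.nan)
    med = float(np.median(x))
    lo = int(stats.binom.ppf(0.025, n, 0.5))
    hi = int(min(stats.binom.ppf(0.975, n, 0.5), n - 1))
    return (med, float(x[lo]), float(x[hi]))


def width_maps(samples: pd.DataFrame, shape: tuple,
               params: WidthParams | None = None) -> dict:
    """Median width per (x, y) lattice column and per z slice, with 95% CIs."""
    params = params or WidthParams()
    nz, ny, nx = shape
    col = np.full((ny, nx), np.nan)
    for (y, x), grp in samples.groupby(["y", "x"]):
        col[int(y), int(x)] = np.median(grp.width_um)
    per_z = []
    for z, grp in samples.groupby("z"):
        med, lo, hi = _median_ci(grp.width_um.to_numpy())
        per_z.append((int(z), med, lo, hi, len(grp)))
    per_z = pd.DataFrame(per_z, columns=["z", "median_um", "ci_lo", "ci_hi", "n"])
    return {"column_median": col, "per_z": per_z}
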