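"""Phase VII: fascicle segmentation by double-angle watershed with merging.

Orientations are headless, so similarity between two unit directions u, v is
measured by the squared scalar product (u . v)^2.  Gaussian-smoothed
*double-angle* maps turn the neighbourhood sums of these similarities into
plain convolutions:

* 2D: v' = (cos 2theta, sin 2theta) and I_w(p) = |(G * V'_w)(p)|^2 equals
  sum_jk g_j g_k w_j w_k (2 (v_j . v_k)^2 - 1);
* 3D: v^(i) = 2 v_i v - e_i doubles the angle from axis i (i = x, y, z), and
  I_w(p) = (sum_i |(G * V_w^(i))(p)|^2 - ((G * W)(p))^2) / 2 equals the same
  double sum with the vectors' 3D scalar products.

The pairwise pool-comparison function f(p, q) — the Gaussian-weighted mean
of (v_j . u_k)^2 over the two neighbourhoods, 1 for equal and 0 for
perpendicular homogeneous fields — has matching closed forms in the cached
convolutions, so watershed merging costs O(1) per pool pair.

The watershed floods points in order of decreasing local anisotropy; a point
adjacent to several pools becomes a watershed (boundary) point only when
some pair of pool maxima has f < f_min, otherwise the pools merge through
it.  In 3D the Gaussian scale is chosen per voxel by penalized smoothing
(d = lambda sigma^2 + epsilon^2 over a sigma grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Seg2DParams, Seg3DParams
from .regions import CAT_PLANAR, CAT_VERTICAL, RegionalSlide

__all__ = [
    "gaussian_kernel1d", "smooth", "watershed_merge",
    "grey_2d", "merge_f_2d", "segment_2d",
    "double_angle_3d", "grey_3d", "merge_f_3d", "adaptive_sigma", "segment_3d",
]


def gaussian_kernel1d(sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Discrete Gaussian truncated at ``truncate`` sigmas, renormalized to 1."""
    r = max(int(np.ceil(truncate * sigma)), 1)
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


def smooth(arr: np.ndarray, sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Separable Gaussian convolution with zero padding (empty outside frame)."""
    g = gaussian_kernel1d(sigma, truncate)
    out = arr.astype(np.float64)
    for ax in range(arr.ndim):
        out = ndimage.convolve1d(out, g, axis=ax, mode="constant", cval=0.0)
    return out


# ---------------------------------------------------------------------------
# watershed with merging

def watershed_merge(values: np.ndarray, allowed: np.ndarray, f_pairs,
                    f_min: float) -> np.ndarray:
    """Flood ``values`` in descending order; merge pools through well-matched
    boundaries.

    ``f_pairs(i, j)`` compares the flat indices of two pool maxima (the first
    point of each pool in the descending order).  Returns an int32 label
    array: 0 excluded, -1 watershed, >= 1 pool ids.  Deterministic: ties in
    value break by raster index.
    """
    shape = values.shape
    flat_vals = values.ravel()
    idx = np.nonzero(allowed.ravel())[0]
    order = idx[np.lexsort((idx, -flat_vals[idx]))]
    labels = np.zeros(values.size, dtype=np.int32)
    parent: list[int] = [0]          # union-find over pool ids (1-based)
    maxima: list[int] = [0]          # flat index of each pool's first point
    fmemo: dict = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    coords = np.array(np.unravel_index(order, shape)).T
    dims = np.array(shape)
    offs = []
    for ax in range(len(shape)):
        for d in (-1, 1):
            o = np.zeros(len(shape), dtype=int)
            o[ax] = d
            offs.append(o)
    for k, p in enumerate(order):
        c = coords[k]
        roots = []
        for o in offs:
            q = c + o
            if np.any(q < 0) or np.any(q >= dims):
                continue
            fq = int(np.ravel_multi_index(tuple(q), shape))
            lq = labels[fq]
            if lq > 0:
                r = find(lq)
                if r not in roots:
                    roots.append(r)
        if not roots:
            parent.append(len(parent))
            maxima.append(int(p))
            labels[p] = len(parent) - 1
        elif len(roots) == 1:
            labels[p] = roots[0]
        else:
            split = False
            for a in range(len(roots)):
                for b in range(a + 1, len(roots)):
                    ia, ib = maxima[roots[a]], maxima[roots[b]]
                    key = (min(ia, ib), max(ia, ib))
                    if key not in fmemo:
                        fmemo[key] = f_pairs(ia, ib)
                    if fmemo[key] < f_min:
                        split = True
                        break
                if split:
                    break
            if split:
                labels[p] = -1
            else:
                keep = min(roots)     # pool created earliest keeps its maximum
                for r in roots:
                    parent[r] = keep
                labels[p] = keep
    out = labels.copy()
    pos = out > 0
    out[pos] = [find(v) for v in out[pos]]
    # compact pool ids to 1..n in order of first appearance
    remap: dict = {}
    flat = out[pos]
    new = np.empty_like(flat)
    nxt = 1
    for i, v in enumerate(flat):
        if v not in remap:
            remap[v] = nxt
            nxt += 1
        new[i] = remap[v]
    out[pos] = new
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# two dimensions

@dataclass
class Seg2D:
    """Cached 2D segmentation fields."""

    gv: np.ndarray            # (H, W, 2) G * V'_w
    iw: np.ndarray            # |G * V'_w|^2
    gw: np.ndarray            # G * W (planar counts)
    vertical_edges: np.ndarray
    masked: np.ndarray        # I_w below the planar grey threshold
    params: Seg2DParams = field(default_factory=Seg2DParams)


def grey_2d(slide: RegionalSlide, params: Seg2DParams | None = None) -> Seg2D:
    """Vertical-channel edges and planar anisotropy image of one slide."""
    params = params or Seg2DParams()
    sigma = float(np.sqrt(params.gaussian_var))
    cat = slide.category
    vert = np.where(cat == CAT_VERTICAL, slide.count, 0.0).astype(np.float64)
    sm = smooth(vert, sigma, params.truncate_sigmas)
    above = sm >= params.vertical_grey_threshold
    below = ~above
    dil = ndimage.binary_dilation(above, structure=np.ones((3, 3), bool))
    vertical_edges = below & dil
    pl = cat == CAT_PLANAR
    th = np.deg2rad(np.nan_to_num(slide.theta, nan=0.0) * 2.0)
    w = np.where(pl, slide.count, 0.0).astype(np.float64)
    vwx = w * np.cos(th) * pl
    vwy = w * np.sin(th) * pl
    gv = np.stack([smooth(vwx, sigma, params.truncate_sigmas),
                   smooth(vwy, sigma, params.truncate_sigmas)], axis=-1)
    iw = (gv**2).sum(axis=-1)
    gw = smooth(w, sigma, params.truncate_sigmas)
    return Seg2D(gv=gv, iw=iw, gw=gw, vertical_edges=vertical_edges,
                 masked=iw < params.planar_grey_threshold, params=params)


def merge_f_2d(p_flat: int, q_flat: int, cached: Seg2D) -> float:
    """Closed-form pool comparison: f = 0 for perpendicular, 1 for aligned.

    Equals the Gaussian/weight-normalized double sum of squared scalar
    products between the two neighbourhoods; f = 0 where either
    neighbourhood carries no weight (no merging through empty tissue).
    """
    shape = cached.iw.shape
    pi = np.unravel_index(p_flat, shape)
    qi = np.unravel_index(q_flat, shape)
    den = 4.0 * cached.gw[pi] * cached.gw[qi]
    if den == 0:
        return 0.0
    num = ((cached.gv[pi] + cached.gv[qi])**2).sum() \
        - cached.iw[pi] - cached.iw[qi]
    return float(num / den + 0.5)


def segment_2d(slide: RegionalSlide, params: Seg2DParams | None = None) -> dict:
    """Watershed-with-merging of one slide; returns labels and edge masks."""
    params = params or Seg2DParams()
    cached = grey_2d(slide, params)
    labels = watershed_merge(cached.iw, ~cached.masked,
                             lambda a, b: merge_f_2d(a, b, cached),
                             params.f_min)
    edges = (labels == -1) | cached.vertical_edges
    return {"labels": labels, "edges": edges, "cached": cached}


# ---------------------------------------------------------------------------
# three dimensions

def double_angle_3d(vec: np.ndarray) -> np.ndarray:
    """The three double-angle maps v^(i) = 2 v_i v - e_i; (..., 3, 3) array.

    Doubling the angle from axis i maps a headless unit field to a vector
    field that convolves meaningfully; zero vectors stay zero.
    """
    out = np.zeros(vec.shape[:-1] + (3, 3), dtype=np.float64)
    nz = (vec**2).sum(-1) > 1e-12
    for i in range(3):
        out[..., i, :] = 2.0 * vec[..., i:i + 1] * vec
        out[..., i, i] -= 1.0
        out[..., i, :] *= nz[..., None]
    return out


@dataclass
class Seg3D:
    """Cached 3D segmentation fields (per-voxel kernel scale)."""

    gvi: np.ndarray           # (Z, H, W, 3, 3) G * V_w^(i)
    gw: np.ndarray            # G * W
    iw: np.ndarray
    sigma: np.ndarray
    params: Seg3DParams = field(default_factory=Seg3DParams)


def grey_3d(vec: np.ndarray, weight: np.ndarray,
            sigma: float | np.ndarray = 1.0,
            params: Seg3DParams | None = None) -> Seg3D:
    """Weighted 3D anisotropy volume and cached convolutions.

    ``sigma`` may be a scalar or a per-voxel map (adaptive smoothing); in the
    latter case each voxel's cached values use its own kernel.  Unit vectors
    are required wherever weight > 0.
    """
    params = params or Seg3DParams()
    norms = np.sqrt((vec**2).sum(-1))
    on = weight > 0
    if on.any() and not np.allclose(norms[on], 1.0, atol=1e-6):
        raise ValueError("non-unit vector with positive weight")
    da = double_angle_3d(vec) * weight[..., None, None]
    sig = np.asarray(sigma, dtype=float)
    if sig.ndim == 0:
        gvi = np.empty_like(da)
        for i in range(3):
            for c in range(3):
                gvi[..., i, c] = smooth(da[..., i, c], float(sig),
                                        params.truncate_sigmas)
        gw = smooth(weight, float(sig), params.truncate_sigmas)
    else:
        uniq = np.unique(np.round(sig, 6))
        gvi = np.zeros_like(da)
        gw = np.zeros_like(weight, dtype=np.float64)
        for s in uniq:
            m = np.isclose(sig, s)
            for i in range(3):
                for c in range(3):
                    gvi[..., i, c][m] = smooth(da[..., i, c], float(s),
                                               params.truncate_sigmas)[m]
            gw[m] = smooth(weight, float(s), params.truncate_sigmas)[m]
    iw = ((gvi**2).sum(axis=(-2, -1)) - gw**2) / 2.0
    return Seg3D(gvi=gvi, gw=gw, iw=iw,
                 sigma=np.broadcast_to(sig, weight.shape).copy(), params=params)


def merge_f_3d(p_flat: int, q_flat: int, cached: Seg3D) -> float:
    """Closed-form 3D pool comparison from the cached convolutions."""
    shape = cached.gw.shape
    pi = np.unravel_index(p_flat, shape)
    qi = np.unravel_index(q_flat, shape)
    den = 4.0 * cached.gw[pi] * cached.gw[qi]
    if den == 0:
        return 0.0
    num = (cached.gvi[pi] * cached.gvi[qi]).sum()
    return float(num / den + 0.25)


def adaptive_sigma(vec: np.ndarray, weight: np.ndarray,
                   params: Seg3DParams | None = None) -> np.ndarray:
    """Per-voxel Gaussian scale minimizing d = lambda sigma^2 + epsilon^2.

    epsilon^2 sums the squared smoothing residual of the weighted
    double-angle maps over the first-order neighbourhood (the voxel and its
    six face neighbours).  Ties break to the smaller sigma.
    """
    params = params or Seg3DParams()
    da = double_angle_3d(vec) * weight[..., None, None]
    grid = np.arange(params.sigma_min, params.sigma_max + params.sigma_step / 2,
                     params.sigma_step)
    foot = np.zeros((3, 3, 3), bool)
    foot[1, 1, 1] = True
    foot[0, 1, 1] = foot[2, 1, 1] = foot[1, 0, 1] = foot[1, 2, 1] = True
    foot[1, 1, 0] = foot[1, 1, 2] = True
    best_d = np.full(weight.shape, np.inf)
    best_s = np.full(weight.shape, grid[0])
    for s in grid:
        resid = np.zeros(weight.shape, dtype=np.float64)
        for i in range(3):
            for c in range(3):
                sm = smooth(da[..., i, c], float(s), params.truncate_sigmas)
                resid += (sm - da[..., i, c])**2
        eps2 = ndimage.correlate(resid, foot.astype(np.float64),
                                 mode="constant", cval=0.0)
        d = params.lam * s * s + eps2
        upd = d < best_d - 1e-15
        best_d[upd] = d[upd]
        best_s[upd] = s
    return np.round(best_s, 6)


def segment_3d(vec: np.ndarray, weight: np.ndarray,
               params: Seg3DParams | None = None,
               adaptive: bool = True) -> dict:
    """Adaptive-scale 3D watershed-with-merging over the tissue voxels."""
    params = params or Seg3DParams()
    sig = adaptive_sigma(vec, weight, params) if adaptive else 1.0
    cached = grey_3d(vec, weight, sig, params)
    labels = watershed_merge(cached.iw, weight > 0,
                             lambda a, b: merge_f_3d(a, b, cached),
                             params.f_min)
    return {"labels": labels, "edges": labels == -1, "cached": cached,
            "sigma": cached.sigma}
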