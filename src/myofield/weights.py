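"""Phase VI: voxel weights from nuclear density and orientation homogeneity.

Density weighting corrects the in-plane nuclear count for the stereological
sampling bias: a nucleus at elevation phi intersects a section plane with
probability h(phi)/l, where h(phi) ~ max(r_M sin phi, r_m) is its projected
height (r_M, r_m the nuclear axes, l the voxel length).  The total count in
a voxel is therefore inferred as

    N = min(N_p / (0.3 |d_z|), N_p / 0.1)

from the mean plane count N_p and the z-component d_z of the assigned
direction, and weighted by a trapezoidal plausibility window: w_d = N/N0
below N0 = 10, 1 between N0 and N1 = 160, 0 above N1 (too dense for smooth
muscle).

Homogeneity weighting measures how aligned the individual nuclear angles in
a voxel are, on the double-angle sphere so headless directions average
correctly: w_h = |sum_theta v(theta, phi)|^2 / |S|^2 with
v(theta, phi) = (sin phi cos 2theta, sin phi sin 2theta, cos phi), phi here
the co-latitude (cos phi = |d_z|).  The voxel weight is w_d * w_h.
"""

from __future__ import annotations

import numpy as np

from .config import DensityParams
from .regions import CAT_EMPTY

__all__ = ["density_weight", "homogeneity_weight", "voxel_weights"]


def density_weight(n_plane, dz, params: DensityParams | None = None):
    """Inferred total count N and density weight w_d; vectorized.

    ``n_plane`` is the mean cross-sectional count, ``dz`` the |z| component
    of the voxel direction.  dz = 0 is harmless: the minor-axis floor (the
    second branch of the min) bounds the correction.
    """
    params = params or DensityParams()
    n_plane = np.asarray(n_plane, dtype=float)
    dz = np.abs(np.asarray(dz, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        n_major = np.where(dz > 0, n_plane / (params.rM_over_l * dz), np.inf)
    n = np.minimum(n_major, n_plane / params.rm_over_l)
    w = np.where(n <= params.N0, n / params.N0,
                 np.where(n > params.N1, 0.0, 1.0))
    if np.isscalar(dz) or n.ndim == 0:
        return float(n), float(w)
    return n, w


def homogeneity_weight(thetas, phi_elevation_deg: float) -> float:
    """Mean-resultant-length-squared alignment of nuclear angles in a voxel.

    ``thetas`` are the planar nuclear angles (deg, headless); the voxel's
    elevation is converted to the co-latitude the double-angle map uses.
    Empty voxels weigh 0; identical angles weigh 1 for any elevation.
    """
    th = np.asarray(thetas, dtype=float)
    if th.size == 0:
        return 0.0
    colat = np.deg2rad(90.0 - abs(phi_elevation_deg))
    t2 = np.deg2rad(2.0 * th)
    v = np.stack([np.sin(colat) * np.cos(t2),
                  np.sin(colat) * np.sin(t2),
                  np.full(th.shape, np.cos(colat))])
    s = v.sum(axis=1)
    return float((s**2).sum() / th.size**2)


def voxel_weights(volume, direction, params: DensityParams | None = None,
                  nuclei_params=None) -> dict:
    """Per-voxel weights for an assembled volume with assigned directions.

    Returns a dict with ``w_d``, ``w_h``, ``weight`` (their product) and the
    inferred total count ``N``.  The homogeneity term pools the registered
    nuclear angles (smooth-muscle size range) per voxel.
    """
    params = params or DensityParams()
    cat = volume.category
    nz, ny, nx = cat.shape
    dz = np.abs(direction.vec[..., 2])
    n, w_d = density_weight(volume.count, dz, params)
    w_h = np.zeros(cat.shape, dtype=np.float64)
    for z, nuc in enumerate(volume.nuclei):
        t = nuc[nuc.sm]
        ix = np.floor(t.x.to_numpy(dtype=float)).astype(np.int64)
        iy = np.floor(t.y.to_numpy(dtype=float)).astype(np.int64)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix, iy = ix[ok], iy[ok]
        th = t.theta_deg.to_numpy(dtype=float)[ok]
        colat = np.deg2rad(90.0 - np.abs(np.nan_to_num(direction.phi[z])))
        t2 = np.deg2rad(2.0 * th)
        flat = iy * nx + ix
        order = np.argsort(flat, kind="stable")
        flat, t2s = flat[order], t2[order]
        sin_c = np.sin(colat).ravel()
        cos_c = np.cos(colat).ravel()
        sx = np.zeros(ny * nx)
        sy = np.zeros(ny * nx)
        cnt = np.zeros(ny * nx)
        np.add.at(sx, flat, np.cos(t2s))
        np.add.at(sy, flat, np.sin(t2s))
        np.add.at(cnt, flat, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = ((sin_c * sx)**2 + (sin_c * sy)**2 + (cos_c * cnt)**2) \
                / np.maximum(cnt, 1)**2
        res[cnt == 0] = 0.0
        w_h[z] = res.reshape(ny, nx)
    w_h[cat == CAT_EMPTY] = 0.0
    w_d = np.where(cat == CAT_EMPTY, 0.0, w_d)
    return {"N": n, "w_d": w_d, "w_h": w_h, "weight": w_d * w_h}
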