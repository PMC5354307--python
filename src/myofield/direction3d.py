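"""Phase V: assigning full 3D headless directions to voxels.

Planar voxels carry an in-plane angle theta but an unknown elevation phi;
vertical voxels carry neither.  Both are resolved by consistency
maximisation against inferred bundle boundaries: for a candidate direction
v the volume is walked voxel by voxel in both directions simultaneously
(steps lambda_i - lambda_{i-1} = min_j 1/|v_j| so consecutive points land in
adjacent voxels) and the walk stops at the first voxel that is no longer in
the same bundle — empty, or differing from the running direction by 30 deg
or more in theta or phi.  The stopping index L(p, v), capped at L_max,
scores candidate directions: longer in-bundle lines are likelier to follow
the true fibre.

Planar voxels are processed in descending s(p) = |L(p, v+) - L(p, v-)|
(probes at +-60 deg elevation on their own theta) so that confidently
determined voxels are assigned first and guide the rest; the elevation is
the L-weighted mean of the candidate grid {-60, -45, ..., 60}, using only
probes longer than 2 voxels.  Vertical voxels follow, ordered by the
largest pairwise L difference over four 45-deg probes; for each candidate
planar angle (11.25-deg grid) an elevation in [30, 90] is averaged the same
way and the angle with the longest resulting line wins.

Directions use v = (cos theta cos phi, sin theta cos phi, sin phi), with phi
the elevation from the slide plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import Direction3DParams
from .regions import CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL

__all__ = ["DirectionVolume", "line_length", "assign_planar_z",
           "assign_vertical", "assign_directions"]

_EMPTY, _PLANAR, _VERTICAL = CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL


@dataclass
class DirectionVolume:
    """Headless unit direction field with polar bookkeeping.

    ``vec`` is (Z, H, W, 3) with components (x, y, z); zero where empty.
    ``theta``/``phi`` are the polar angles actually assigned; ``confident``
    is False where a voxel had no in-bundle probe at all (degenerate default).
    """

    vec: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    confident: np.ndarray


@njit(cache=True)
def _circ360(a, b):
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


@njit(cache=True)
def _axial180(a, b):
    d = abs((a - b) % 180.0)
    return min(d, 180.0 - d)


@njit(cache=True)
def _same_bundle_assigned(th1, ph1, th_u, ph_u, lim):
    """Headless 30-deg comparison of two assigned polar directions."""
    if _circ360(th1, th_u) < lim and abs(ph1 - ph_u) < lim:
        return True
    return _circ360(th1 + 180.0, th_u) < lim and abs(-ph1 - ph_u) < lim


@njit(cache=True)
def _line_length(cat, th, asg, ath, aph, z0, y0, x0, thv, phv, lmax, min_len):
    """L(p, v): simultaneous two-arm walk, stopping at the shared index."""
    nz, ny, nx = cat.shape
    rth = np.deg2rad(thv)
    rph = np.deg2rad(phv)
    vx = np.cos(rth) * np.cos(rph)
    vy = np.sin(rth) * np.cos(rph)
    vz = np.sin(rph)
    m = max(abs(vx), max(abs(vy), abs(vz)))
    if m <= 0.0:
        return 0
    step = 1.0 / m
    # per-arm running direction (polar), initialised by the temporary rule at p
    cat0 = cat[z0, y0, x0]
    if asg[z0, y0, x0]:
        tpu = ath[z0, y0, x0]
        ppu = aph[z0, y0, x0]
    elif cat0 == _PLANAR:
        tpu = th[z0, y0, x0]
        ppu = phv
    else:
        tpu = thv
        ppu = phv
    tmu, pmu = tpu, ppu
    for i in range(1, lmax + 1):
        lam = step * i
        for arm in range(2):
            sgn = 1.0 if arm == 0 else -1.0
            x = x0 + sgn * lam * vx
            y = y0 + sgn * lam * vy
            z = z0 + sgn * lam * vz
            xi = int(np.rint(x))
            yi = int(np.rint(y))
            zi = int(np.rint(z))
            if xi < 0 or xi >= nx or yi < 0 or yi >= ny or zi < 0 or zi >= nz:
                return i
            c = cat[zi, yi, xi]
            if c == _EMPTY:
                return i
            tu = tpu if arm == 0 else tmu
            pu = ppu if arm == 0 else pmu
            if asg[zi, yi, xi]:
                if not _same_bundle_assigned(ath[zi, yi, xi], aph[zi, yi, xi],
                                             tu, pu, 30.0):
                    return i
                nt = ath[zi, yi, xi]
                npp = aph[zi, yi, xi]
            elif c == _PLANAR:
                if _axial180(th[zi, yi, xi], tu) >= 30.0:
                    return i
                nt = th[zi, yi, xi]
                npp = phv
            else:  # vertical
                if abs(pu) <= 30.0:
                    return i
                nt = thv
                npp = phv
            if arm == 0:
                tpu, ppu = nt, npp
            else:
                tmu, pmu = nt, npp
    return lmax


@njit(cache=True)
def _phi_average(cat, th, asg, ath, aph, z, y, x, theta, phis, lmax, min_len,
                 fallback):
    num = 0.0
    den = 0.0
    best_l = 0
    for i in range(len(phis)):
        li = _line_length(cat, th, asg, ath, aph, z, y, x, theta, phis[i],
                          lmax, min_len)
        if li > best_l:
            best_l = li
        if li > min_len:
            num += li * phis[i]
            den += li
    if den > 0.0:
        return num / den, best_l, True
    return fallback, best_l, False


@njit(cache=True)
def _planar_pass(cat, th, asg, ath, aph, order_z, order_y, order_x,
                 phis, lmax, min_len, conf):
    for k in range(len(order_z)):
        z, y, x = order_z[k], order_y[k], order_x[k]
        phi, _, ok = _phi_average(cat, th, asg, ath, aph, z, y, x,
                                  th[z, y, x], phis, lmax, min_len, 0.0)
        ath[z, y, x] = th[z, y, x]
        aph[z, y, x] = phi
        asg[z, y, x] = True
        conf[z, y, x] = ok


@njit(cache=True)
def _vertical_pass(cat, th, asg, ath, aph, order_z, order_y, order_x,
                   thetas, phis, lmax, min_len, conf):
    for k in range(len(order_z)):
        z, y, x = order_z[k], order_y[k], order_x[k]
        best_theta = 0.0
        best_phi = 90.0
        best_l = -1
        any_ok = False
        for i in range(len(thetas)):
            phi, _, ok = _phi_average(cat, th, asg, ath, aph, z, y, x,
                                      thetas[i], phis, lmax, min_len, 90.0)
            li = _line_length(cat, th, asg, ath, aph, z, y, x,
                              thetas[i], phi, lmax, min_len)
            any_ok = any_ok or ok
            if li > best_l:
                best_l = li
                best_theta = thetas[i]
                best_phi = phi
        ath[z, y, x] = best_theta
        aph[z, y, x] = best_phi
        asg[z, y, x] = True
        conf[z, y, x] = any_ok


@njit(cache=True)
def _planar_scores(cat, th, asg, ath, aph, zz, yy, xx, lmax, min_len):
    s = np.zeros(len(zz), dtype=np.int64)
    for k in range(len(zz)):
        z, y, x = zz[k], yy[k], xx[k]
        lp = _line_length(cat, th, asg, ath, aph, z, y, x, th[z, y, x], 60.0,
                          lmax, min_len)
        lm = _line_length(cat, th, asg, ath, aph, z, y, x, th[z, y, x], -60.0,
                          lmax, min_len)
        s[k] = abs(lp - lm)
    return s


@njit(cache=True)
def _vertical_scores(cat, th, asg, ath, aph, zz, yy, xx, lmax, min_len):
    s = np.zeros(len(zz), dtype=np.int64)
    probes_th = np.array([0.0, 180.0, 90.0, 270.0])
    for k in range(len(zz)):
        z, y, x = zz[k], yy[k], xx[k]
        ls = np.zeros(4, dtype=np.int64)
        for j in range(4):
            ls[j] = _line_length(cat, th, asg, ath, aph, z, y, x,
                                 probes_th[j], 45.0, lmax, min_len)
        m = 0
        for a in range(4):
            for b in range(a + 1, 4):
                d = abs(ls[a] - ls[b])
                if d > m:
                    m = d
        s[k] = m
    return s


def line_length(volume_cat, volume_theta, p, theta_deg, phi_deg,
                params: Direction3DParams | None = None,
                assigned=None, a_theta=None, a_phi=None) -> int:
    """Public probe: distance (in steps) to the inferred bundle boundary."""
    params = params or Direction3DParams()
    cat = np.ascontiguousarray(volume_cat.astype(np.uint8))
    th = np.ascontiguousarray(np.nan_to_num(volume_theta).astype(np.float64))
    asg = np.zeros(cat.shape, dtype=np.bool_) if assigned is None \
        else assigned.astype(np.bool_)
    ath = np.zeros(cat.shape) if a_theta is None else a_theta.astype(np.float64)
    aph = np.zeros(cat.shape) if a_phi is None else a_phi.astype(np.float64)
    if np.cos(np.deg2rad(phi_deg)) == 0 and np.sin(np.deg2rad(phi_deg)) == 0:
        raise ValueError("zero direction")
    z, y, x = p
    return int(_line_length(cat, th, asg, ath, aph, int(z), int(y), int(x),
                            float(theta_deg), float(phi_deg),
                            params.l_max, params.min_length))


def _prep(volume_cat, volume_theta):
    cat = np.ascontiguousarray(volume_cat.astype(np.uint8))
    th = np.ascontiguousarray(np.nan_to_num(volume_theta).astype(np.float64))
    asg = np.zeros(cat.shape, dtype=np.bool_)
    ath = np.zeros(cat.shape, dtype=np.float64)
    aph = np.zeros(cat.shape, dtype=np.float64)
    conf = np.zeros(cat.shape, dtype=np.bool_)
    return cat, th, asg, ath, aph, conf


def _ordered(zz, yy, xx, s):
    order = np.lexsort((xx, yy, zz, -s))   # descending s, raster-order ties
    return zz[order], yy[order], xx[order]


def assign_planar_z(volume_cat, volume_theta,
                    params: Direction3DParams | None = None,
                    state=None):
    """Elevation assignment for all planar voxels (in descending s order)."""
    params = params or Direction3DParams()
    cat, th, asg, ath, aph, conf = state or _prep(volume_cat, volume_theta)
    zz, yy, xx = np.nonzero(cat == _PLANAR)
    if len(zz):
        s = _planar_scores(cat, th, asg, ath, aph, zz, yy, xx,
                           params.l_max, params.min_length)
        oz, oy, ox = _ordered(zz, yy, xx, s)
        phis = np.arange(-60.0, 60.1, params.planar_phi_step)
        _planar_pass(cat, th, asg, ath, aph, oz, oy, ox, phis,
                     params.l_max, params.min_length, conf)
    return cat, th, asg, ath, aph, conf


def assign_vertical(state, params: Direction3DParams | None = None):
    """Full (theta, phi) assignment for all vertical voxels."""
    params = params or Direction3DParams()
    cat, th, asg, ath, aph, conf = state
    zz, yy, xx = np.nonzero(cat == _VERTICAL)
    if len(zz):
        s = _vertical_scores(cat, th, asg, ath, aph, zz, yy, xx,
                             params.l_max, params.min_length)
        oz, oy, ox = _ordered(zz, yy, xx, s)
        thetas = np.arange(0.0, 360.0, params.vertical_theta_step)
        phis = np.arange(30.0, 90.1, params.planar_phi_step)
        _vertical_pass(cat, th, asg, ath, aph, oz, oy, ox, thetas, phis,
                       params.l_max, params.min_length, conf)
    return state


def assign_directions(volume_cat, volume_theta,
                      params: Direction3DParams | None = None) -> DirectionVolume:
    """Planar pass then vertical pass; returns the unit direction field."""
    params = params or Direction3DParams()
    state = assign_planar_z(volume_cat, volume_theta, params)
    cat, th, asg, ath, aph, conf = assign_vertical(state, params)
    rth = np.deg2rad(ath)
    rph = np.deg2rad(aph)
    vec = np.zeros(cat.shape + (3,), dtype=np.float64)
    nonempty = cat != _EMPTY
    vec[..., 0] = np.where(nonempty, np.cos(rth) * np.cos(rph), 0.0)
    vec[..., 1] = np.where(nonempty, np.sin(rth) * np.cos(rph), 0.0)
    vec[..., 2] = np.where(nonempty, np.sin(rph), 0.0)
    theta = np.where(nonempty, ath, np.nan)
    phi = np.where(nonempty, aph, np.nan)
    return DirectionVolume(vec=vec, theta=theta, phi=phi,
                           confident=conf & nonempty)
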