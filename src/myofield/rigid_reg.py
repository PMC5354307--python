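"""Phase III (rigid): whole-slide alignment by generalized Hough optimisation.

Each slide is aligned to its predecessor by alternating translation and
rotation searches over Canny edges of the nuclear-count image.  The
translation Hough space is the accumulator of integer offsets t = q - p over
edge-point pairs; the rotation Hough space is an angular-shift accumulator in
polar coordinates about a step-dependent grid of rotation centres.  Seven
transformation steps progressively narrow the search bounds (translation
±W/2^i; rotation ±180, ±10, ±5, ±2.5, ±1.25, ±1, ±1 deg), with at most 10
translate+rotate iterations per step.

Edge coincidence counts a hit when a transformed point lands within 1 px
(1 polar bin) of a target edge point.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, signal
from skimage import feature

from .config import EdgeParams, RigidParams
from .regions import RegionalSlide, rebuild

__all__ = ["RigidTransform", "edge_image", "hough_translate", "hough_rotate",
           "register_pair", "rigid_register_stack", "coincidence"]


@dataclass
class RigidTransform:
    """Affine rigid map T(p) = A p + b accumulated from rotations/translations."""

    A: np.ndarray = dc_field(default_factory=lambda: np.eye(2))
    b: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def rotation(cls, theta_deg: float, centre) -> "RigidTransform":
        th = np.deg2rad(theta_deg)
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(centre, dtype=float)
        return cls(A, c - A @ c)

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls(np.eye(2), np.asarray(t, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other))(p) = self(other(p))."""
        return RigidTransform(self.A @ other.A, self.A @ other.b + self.b)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.A.T + self.b

    @property
    def theta_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.A[1, 0], self.A[0, 0])))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(self.theta_deg) < tol and float(np.abs(self.b).max()) < tol


def edge_image(slide: RegionalSlide, params: EdgeParams | None = None) -> np.ndarray:
    """Canny edges of the scaled nuclear-count image; (N, 2) int (x, y) points."""
    params = params or EdgeParams()
    grey = np.clip(slide.count * params.count_scale, 0, 255).astype(np.float64)
    if not grey.any():
        return np.zeros((0, 2), dtype=np.int64)
    e = feature.canny(grey, sigma=params.gaussian_sd,
                      low_threshold=params.hysteresis_low,
                      high_threshold=params.hysteresis_high)
    ys, xs = np.nonzero(e)
    return np.column_stack([xs, ys]).astype(np.int64)


def _edge_raster(pts: np.ndarray, shape: tuple[int, int],
                 dilate: bool = False) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    p = np.rint(pts).astype(np.int64)
    ok = (p[:, 0] >= 0) & (p[:, 0] < shape[1]) & (p[:, 1] >= 0) & (p[:, 1] < shape[0])
    img[p[ok, 1], p[ok, 0]] = 1.0
    if dilate:
        img = ndimage.grey_dilation(img, size=(3, 3))
    return img


def hough_translate(e1: np.ndarray, e0: np.ndarray, bound: int,
                    frame_shape: tuple[int, int]) -> tuple[int, int]:
    """Integer offset |t|_inf <= bound maximizing coincidence of e1 + t with e0.

    Computed as the cross-correlation of the two edge rasters (e0 dilated by
    1 px for the matching tolerance); ties break to the smallest |t|, then
    lexicographically on (tx, ty).
    """
    if len(e1) == 0 or len(e0) == 0:
        raise ValueError("no edges")
    h, w = frame_shape
    i1 = _edge_raster(e1, frame_shape)
    i0 = _edge_raster(e0, frame_shape, dilate=True)
    # corr[ty + h - 1, tx + w - 1] = sum_p i1(p) * i0(p + t)
    corr = signal.fftconvolve(i0, i1[::-1, ::-1], mode="full")
    counts = np.rint(corr).astype(np.int64)
    b = int(bound)
    ty = np.arange(max(-b, 1 - h), min(b, h - 1) + 1)
    tx = np.arange(max(-b, 1 - w), min(b, w - 1) + 1)
    sub = counts[np.ix_(ty + h - 1, tx + w - 1)]
    best = sub.max()
    iy, ix = np.nonzero(sub == best)
    cand = np.column_stack([tx[ix], ty[iy]]).astype(np.int64)
    order = np.lexsort((cand[:, 1], cand[:, 0], (cand**2).sum(axis=1)))
    sel = cand[order[0]]
    return int(sel[0]), int(sel[1])


def _polar_bins(pts: np.ndarray, centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = pts - centre
    r = np.rint(np.hypot(d[:, 0], d[:, 1])).astype(np.int64)
    a = np.floor(np.rad2deg(np.arctan2(d[:, 1], d[:, 0])) % 360.0).astype(np.int64) % 360
    return r, a


def _rotation_scores(e1: np.ndarray, e0: np.ndarray, centre: np.ndarray,
                     shifts: np.ndarray) -> np.ndarray:
    """Coincidence count for each angular shift (deg) about ``centre``."""
    r0, a0 = _polar_bins(e0, centre)
    r1, a1 = _polar_bins(e1, centre)
    rmax = int(max(r0.max(initial=0), r1.max(initial=0))) + 2
    occ = np.zeros((rmax + 1, 360), dtype=bool)
    occ[r0, a0] = True
    d = occ.copy()                       # 1-px tolerance: +-1 radial bin
    d[1:] |= occ[:-1]
    d[:-1] |= occ[1:]
    # +-1 angular bin only where a 1-deg bin is narrower than 1 px (r < 60),
    # so the matching radius stays ~1 px at every radius and distant rotation
    # centres gain no artificial tolerance
    near = d[:60].copy()
    near |= np.roll(d[:60], 1, axis=1) | np.roll(d[:60], -1, axis=1)
    d[:60] = near
    cols = (a1[:, None] + shifts[None, :]) % 360
    return d[r1[:, None], cols].sum(axis=0)


def hough_rotate(e1: np.ndarray, e0: np.ndarray, centres: np.ndarray,
                 bound_deg: float, c0: np.ndarray) -> tuple[float, np.ndarray]:
    """Best integer-degree rotation (theta, centre) aligning e1 to e0.

    For each candidate centre the edge sets are mapped to polar coordinates
    (1 px radial, 1 deg angular bins) and the angular shift with the highest
    coincidence is scored.  Ties break to smaller |theta|, then to the centre
    nearest the frame centre c0, then to grid order.
    """
    if len(e1) == 0 or len(e0) == 0:
        raise ValueError("no edges")
    b = int(np.floor(bound_deg))
    shifts = np.arange(-b, b + 1)
    best = None
    for ci, c in enumerate(np.atleast_2d(np.asarray(centres, dtype=float))):
        sc = _rotation_scores(e1, e0, c, shifts)
        top = sc.max()
        idx = np.nonzero(sc == top)[0]
        th = int(shifts[idx[np.lexsort((shifts[idx], np.abs(shifts[idx])))[0]]])
        dist = float(np.hypot(*(c - c0)))
        key = (-int(top), abs(th), dist, ci)
        if best is None or key < best[0]:
            best = (key, float(th), c)
    return best[1], best[2]


def _centre_grid(step: int, frame_shape: tuple[int, int],
                 params: RigidParams) -> np.ndarray:
    h, w = frame_shape
    c0 = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    pitch = params.centre_pitch * step
    if step == 1:
        n = int(params.step1_radius // pitch)
        off = np.arange(-n, n + 1) * pitch
        gx, gy = np.meshgrid(off, off)
        pts = c0 + np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[np.hypot(*(pts - c0).T) <= params.step1_radius]
    else:
        nxp = int(c0[0] // pitch)
        nyp = int(c0[1] // pitch)
        gx, gy = np.meshgrid(np.arange(-nxp, nxp + 1) * pitch,
                             np.arange(-nyp, nyp + 1) * pitch)
        pts = c0 + np.column_stack([gx.ravel(), gy.ravel()])
    order = np.argsort(np.hypot(*(pts - c0).T), kind="stable")
    return pts[order]


def coincidence(e1: np.ndarray, e0: np.ndarray, frame_shape) -> int:
    """Number of e1 points within 1 px of an e0 point (the Hough objective)."""
    i0 = _edge_raster(e0, frame_shape, dilate=True)
    p = np.rint(e1).astype(np.int64)
    ok = (p[:, 0] >= 0) & (p[:, 0] < frame_shape[1]) \
        & (p[:, 1] >= 0) & (p[:, 1] < frame_shape[0])
    return int(i0[p[ok, 1], p[ok, 0]].sum())


def register_pair(e1: np.ndarray, e0: np.ndarray, frame_shape: tuple[int, int],
                  params: RigidParams | None = None,
                  trace: list | None = None) -> RigidTransform:
    """Rigid transform aligning edge set e1 to reference edge set e0."""
    params = params or RigidParams()
    if len(e1) == 0 or len(e0) == 0:
        raise ValueError("no edges")
    h, w = frame_shape
    c0 = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    cur = e1.astype(np.float64)
    total = RigidTransform.identity()
    for step in range(1, params.n_steps + 1):
        tb = max(int(params.frame_w // 2**step), 1)
        rb = params.rotation_bounds[step - 1]
        centres = _centre_grid(step, frame_shape, params)
        for _ in range(params.max_iterations):
            t = hough_translate(cur, e0, tb, frame_shape)
            if t != (0, 0):
                tr = RigidTransform.translation(t)
                cur = tr(cur)
                total = tr.compose(total)
            th, c = hough_rotate(cur, e0, centres, rb, c0)
            if th != 0.0:
                rot = RigidTransform.rotation(th, c)
                cur = rot(cur)
                total = rot.compose(total)
            if trace is not None:
                trace.append((step, t, th, coincidence(cur, e0, frame_shape)))
            if t == (0, 0) and th == 0.0:
                break
    return total


def rigid_register_stack(stack: list[RegionalSlide],
                         params: RigidParams | None = None,
                         edge_params: EdgeParams | None = None
                         ) -> tuple[list[RegionalSlide], list[RigidTransform]]:
    """Register each slide to its (already registered) predecessor.

    Slides with an empty edge image are passed through unregistered and
    flagged.  Returns the transformed stack (nuclei moved, planes rebuilt)
    and the per-slide transforms.
    """
    params = params or RigidParams()
    out = [stack[0]]
    transforms = [RigidTransform.identity()]
    e_prev = edge_image(stack[0], edge_params)
    for slide in stack[1:]:
        e_cur = edge_image(slide, edge_params)
        if len(e_cur) == 0 or len(e_prev) == 0:
            s = rebuild(slide)
            s.flags["rigid_unregistered"] = True
            out.append(s)
            transforms.append(RigidTransform.identity())
            if len(e_cur):
                e_prev = e_cur
            continue
        T = register_pair(e_cur, e_prev, slide.frame_shape, params)
        nuc = slide.nuclei.copy()
        pts = T(np.column_stack([nuc.x.to_numpy(), nuc.y.to_numpy()]))
        nuc["x"], nuc["y"] = pts[:, 0], pts[:, 1]
        nuc["theta_deg"] = (nuc.theta_deg + T.theta_deg) % 180.0
        s = rebuild(slide, nuc)
        out.append(s)
        transforms.append(T)
        e_prev = edge_image(s, edge_params)
    return out, transforms
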