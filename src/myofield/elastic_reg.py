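"""Phase III (elastic): locally rigid per-tile registration and slide ordering.

After rigid alignment, each slide is registered to a reference slide tile by
tile (16 x 16 region pixels).  Each tile's *area of interest* grows by rings
of tiles until the directional heterogeneity of the area reaches (45 deg)^2,
so homogeneous neighbourhoods cannot lock onto spurious matches.  A tile that
already matches its reference (energy e <= e_min) keeps the identity
transform; otherwise a generalized Hough accumulator over rotation (|theta|
<= 30 deg, 1-deg bins) and translation (|t| <= b(A) = b0 * e(A, T0), 1-px
bins) picks the densest transform, restricted to angle-compatible point
pairs.  A neighbourhood-refinement pass then lets each tile adopt whichever
nearby transform minimizes the summed energy over its 3x3 tile
neighbourhood.  Nuclei are finally warped by the inverse-square-distance
blend of the four nearest tile transforms.

Slide ordering: a global reference slide is chosen inside the densest
substack (the slide with the lowest mean pairwise match score); local
references are picked working outward by best match score to the previous
reference; non-references register to their nearest reference.  Slides whose
post-registration match score exceeds a threshold are flagged for discard —
the automated counterpart of the published visual integrity checks — and
registration re-runs from the last sound reference when a reference fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


from . import angles
from .config import ElasticParams
from .regions import CAT_EMPTY, CAT_PLANAR, RegionalSlide, rebuild

__all__ = [
    "TileTransform", "heterogeneity", "expand_area", "match_energy",
    "register_tile", "register_slide", "apply_warp", "match_score",
    "order_and_register",
]


@dataclass
class TileTransform:
    """Locally rigid tile map T(p) = M_theta (p - centre) + centre + t."""

    theta: float = 0.0
    t: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))
    centre: np.ndarray = dc_field(default_factory=lambda: np.zeros(2))
    energy: float = 0.0

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        th = np.deg2rad(self.theta)
        c, s = np.cos(th), np.sin(th)
        d = pts - self.centre
        return np.column_stack([c * d[:, 0] - s * d[:, 1],
                                s * d[:, 0] + c * d[:, 1]]) + self.centre + self.t

    @property
    def is_identity(self) -> bool:
        return self.theta == 0.0 and not self.t.any()


def heterogeneity(category: np.ndarray, theta: np.ndarray, rect: tuple) -> float:
    """Angle variance (deg^2) of the filled angle sequence S of an area.

    Planar pixels contribute their own angles; every non-planar pixel
    contributes the direction perpendicular to the circular mean of the
    planar angles.  Zero planar pixels give heterogeneity 0.
    """
    y0, y1, x0, x1 = rect
    cat = category[y0:y1, x0:x1]
    th = theta[y0:y1, x0:x1]
    pl = cat == CAT_PLANAR
    n = cat.size
    npl = int(pl.sum())
    if npl == 0:
        return 0.0
    th_pl = th[pl].astype(float)
    mean = angles.circular_mean(th_pl)
    s = np.concatenate([th_pl, np.full(n - npl, (mean + 90.0) % 180.0)])
    return angles.axial_variance(s)


def expand_area(slide: RegionalSlide, tile: tuple[int, int],
                params: ElasticParams, bbox: tuple | None = None) -> tuple:
    """Heterogeneity-driven area of interest around a tile.

    The area grows by one symmetric tile ring per step until its angle
    variance reaches the threshold or it covers the content bounding box
    (pixels beyond the content are empty on every slide and carry no
    registration information).
    """
    tp = params.tile_px
    h, w = slide.frame_shape
    if bbox is None:
        bbox = (0, h, 0, w)
    ty, tx = tile
    ring = 0
    while True:
        rect = (max((ty - ring) * tp, 0), min((ty + 1 + ring) * tp, h),
                max((tx - ring) * tp, 0), min((tx + 1 + ring) * tp, w))
        if heterogeneity(slide.category, slide.theta, rect) >= params.het_threshold_deg2:
            return rect
        if (rect[0] <= bbox[0] and rect[1] >= bbox[1]
                and rect[2] <= bbox[2] and rect[3] >= bbox[3]):
            return rect
        ring += 1


def match_energy(mov: RegionalSlide, ref: RegionalSlide, rect: tuple,
                 transform: TileTransform, params: ElasticParams) -> float:
    """Energy e(A, T) = 1 - (matched pixels) / (area pixels).

    A pixel p is matched when one of the four reference pixels around T(p)
    is non-planar together with p, or is planar together with p with a
    headless angle difference (after adding theta_T) below a_max.  Reference
    pixels outside the frame count as empty.
    """
    y0, y1, x0, x1 = rect
    h, w = ref.frame_shape
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    tp = transform(pts)
    p_planar = (mov.category[y0:y1, x0:x1] == CAT_PLANAR).ravel()
    a_p = mov.theta[y0:y1, x0:x1].ravel() + transform.theta
    qx0 = np.floor(tp[:, 0]).astype(np.int64)
    qy0 = np.floor(tp[:, 1]).astype(np.int64)
    matched = np.zeros(len(tp), dtype=bool)
    for dy in (0, 1):
        for dx in (0, 1):
            qx, qy = qx0 + dx, qy0 + dy
            inside = (qx >= 0) & (qx < w) & (qy >= 0) & (qy < h)
            qc = np.zeros(len(tp), dtype=np.uint8)
            qc[inside] = ref.category[qy[inside], qx[inside]]
            q_planar = qc == CAT_PLANAR
            matched |= ~p_planar & ~q_planar
            both = p_planar & q_planar
            if both.any():
                qa = np.full(len(tp), np.nan)
                qa[inside] = ref.theta[qy[inside], qx[inside]]
                d = angles.axial_distance(qa[both], a_p[both])
                m = np.zeros(len(tp), dtype=bool)
                m[both] = d < params.a_max_deg
                matched |= m
    return 1.0 - matched.mean() if len(tp) else 0.0


def register_tile(mov: RegionalSlide, ref: RegionalSlide, rect: tuple,
                  centre: np.ndarray, e0: float,
                  params: ElasticParams) -> TileTransform:
    """Hough-optimal locally rigid transform for one tile area.

    The accumulator runs over integer-degree rotations and integer-pixel
    translations t = q - M_theta(p - c) - c restricted to angle-compatible
    planar pixel pairs, |theta| <= 30 deg and |t| <= b(A) = b0 * e(A, T0).
    Ties break to the smallest |theta|, then |t|, then lexicographic order.
    """
    y0, y1, x0, x1 = rect
    cat = mov.category[y0:y1, x0:x1]
    pl = cat == CAT_PLANAR
    if not pl.any():
        return TileTransform(centre=centre, energy=e0)
    b = params.b0_px * e0
    bi = int(np.floor(b))
    yy, xx = np.nonzero(pl)
    p = np.column_stack([(xx + x0).astype(float), (yy + y0).astype(float)])
    a1 = mov.theta[y0:y1, x0:x1][pl].astype(float)
    thetas = np.arange(-int(params.theta_bound_deg), int(params.theta_bound_deg) + 1)
    nt = 2 * bi + 1
    acc = np.zeros((len(thetas), nt, nt), dtype=np.int32)
    # rotated copies of the planar points for every candidate angle
    rad = np.deg2rad(thetas)
    cth, sth = np.cos(rad)[:, None], np.sin(rad)[:, None]
    d0 = p - centre
    rot = np.stack([cth * d0[:, 0] - sth * d0[:, 1] + centre[0],
                    sth * d0[:, 0] + cth * d0[:, 1] + centre[1]], axis=-1)
    rp = np.rint(rot).astype(np.int64)          # (ntheta, np, 2)
    # reference sub-raster covering every reachable position (+ |t| margin),
    # padded by bi so offset gathers need no bounds checks
    h, w = ref.frame_shape
    wx0 = max(int(rp[..., 0].min()) - bi, 0) if rp.size else 0
    wx1 = min(int(rp[..., 0].max()) + bi + 1, w) if rp.size else 1
    wy0 = max(int(rp[..., 1].min()) - bi, 0) if rp.size else 0
    wy1 = min(int(rp[..., 1].max()) + bi + 1, h) if rp.size else 1
    sub_cat = ref.category[wy0:wy1, wx0:wx1] == CAT_PLANAR
    sub_ang = ref.theta[wy0:wy1, wx0:wx1]
    wh, ww = sub_cat.shape
    # per-degree-class compatibility stack: class c matches reference pixels
    # whose headless angle is within a_max of c (circular box filter)
    cls_r = np.where(sub_cat,
                     np.rint(np.nan_to_num(sub_ang)).astype(np.int64) % 180, -1)
    onehot = np.zeros((180, wh * ww), dtype=bool)
    sel = cls_r.ravel() >= 0
    onehot[cls_r.ravel()[sel], np.nonzero(sel)[0]] = True
    ww_half = int(np.ceil(params.a_max_deg)) - 1    # |diff| < a_max, integer classes
    idx = (np.arange(180)[:, None] + np.arange(-ww_half, ww_half + 1)[None, :]) % 180
    compat = onehot[idx].any(axis=1)                # (180, wh*ww)
    compat = compat.reshape(180, wh, ww)
    padded = np.zeros((180, wh + 2 * bi, ww + 2 * bi), dtype=bool)
    padded[:, bi:bi + wh, bi:bi + ww] = compat
    tj, ti = np.mgrid[0:nt, 0:nt]
    disc = (tj - bi)**2 + (ti - bi)**2 <= b * b
    for k, th in enumerate(thetas):
        cls = np.rint(a1 + th).astype(np.int64) % 180
        py = rp[k, :, 1] - wy0
        px = rp[k, :, 0] - wx0
        ok = (py >= 0) & (py < wh) & (px >= 0) & (px < ww)
        if not ok.any():
            continue
        patches = padded[cls[ok][:, None, None], py[ok][:, None, None] + tj,
                         px[ok][:, None, None] + ti]
        acc[k] = patches.sum(axis=0)
    acc *= disc
    if acc.max() == 0:
        out = TileTransform(centre=centre, energy=e0)
        out.flag = "no admissible transform"
        return out
    cand = np.column_stack(np.nonzero(acc == acc.max()))
    th = thetas[cand[:, 0]]
    tyv = cand[:, 1] - bi
    txv = cand[:, 2] - bi
    order = np.lexsort((tyv, txv, txv**2 + tyv**2, np.abs(th)))
    sel = cand[order[0]]
    tt = TileTransform(theta=float(thetas[sel[0]]),
                       t=np.array([sel[2] - bi, sel[1] - bi], dtype=float),
                       centre=centre)
    tt.energy = e0
    return tt


def _content_bbox(slide: RegionalSlide) -> tuple:
    ys, xs = np.nonzero(slide.category != CAT_EMPTY)
    if len(ys) == 0:
        h, w = slide.frame_shape
        return (0, h, 0, w)
    return (int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1)


def register_slide(mov: RegionalSlide, ref: RegionalSlide,
                   params: ElasticParams | None = None) -> tuple[RegionalSlide, dict]:
    """Elastically register ``mov`` to ``ref``; returns (warped slide, info).

    info holds the tile-transform grid, per-tile energies and the area
    rectangles (for diagnostics).
    """
    params = params or ElasticParams()
    tp = params.tile_px
    h, w = mov.frame_shape
    nty, ntx = h // tp, w // tp
    ref_has_planar = bool((ref.category == CAT_PLANAR).any())
    bbox = _content_bbox(mov)
    grid: dict = {}
    areas: dict = {}
    occupied = mov.category != CAT_EMPTY
    for ty in range(nty):
        for tx in range(ntx):
            centre = np.array([tx * tp + tp / 2.0, ty * tp + tp / 2.0])
            tile_occ = occupied[ty * tp:(ty + 1) * tp, tx * tp:(tx + 1) * tp]
            if not tile_occ.any():
                grid[(ty, tx)] = TileTransform(centre=centre)
                continue
            rect = expand_area(mov, (ty, tx), params, bbox)
            areas[(ty, tx)] = rect
            ident = TileTransform(centre=centre)
            e0 = match_energy(mov, ref, rect, ident, params)
            if e0 <= params.e_min or not ref_has_planar:
                ident.energy = e0
                grid[(ty, tx)] = ident
                continue
            grid[(ty, tx)] = register_tile(mov, ref, rect, centre, e0, params)
    # neighbourhood refinement: each tile may adopt the neighbour transform
    # minimizing the summed energy over its local neighbourhood of areas
    refined: dict = {}
    r = params.neighbourhood
    for (ty, tx), cur in grid.items():
        if (ty, tx) not in areas:
            refined[(ty, tx)] = cur
            continue
        neigh = [(ty + dy, tx + dx) for dy in range(-r, r + 1)
                 for dx in range(-r, r + 1)]
        neigh = [k for k in neigh if k in areas]
        cands = []
        seen = set()
        for k in neigh:
            tt = grid[k]
            key = (tt.theta, tt.t[0], tt.t[1], tt.centre[0], tt.centre[1])
            if key not in seen:
                seen.add(key)
                cands.append(tt)
        if len(cands) == 1:
            refined[(ty, tx)] = cur
            continue
        best, best_total = None, np.inf
        for tt in cands:
            total = sum(match_energy(mov, ref, areas[k], tt, params) for k in neigh)
            if total < best_total - 1e-12:
                best, best_total = tt, total
        sel = TileTransform(theta=best.theta, t=best.t.copy(),
                            centre=best.centre.copy(), energy=cur.energy)
        refined[(ty, tx)] = sel
    tgrid = np.empty((nty, ntx), dtype=object)
    for (ty, tx), tt in refined.items():
        tgrid[ty, tx] = tt
    nuc = apply_warp(mov.nuclei, tgrid, tile_px=tp)
    out = rebuild(mov, nuc)
    return out, {"tiles": tgrid, "areas": areas}


def apply_warp(nuclei, tile_grid: np.ndarray, tile_px: int = 16):
    """Warp nuclei by inverse-square-distance blending of tile transforms.

    Each point is mapped to sum_i w_i T_i(p) over its four nearest tile
    centres, w_i ~ 1/|p - c_i|^2; a point sitting exactly on a tile centre
    uses that tile's transform alone.  Angles gain the blended rotation.
    """
    nty, ntx = tile_grid.shape
    out = nuclei.copy()
    if not len(nuclei):
        return out
    p = np.column_stack([nuclei.x.to_numpy(dtype=float),
                         nuclei.y.to_numpy(dtype=float)])
    gx = np.clip(np.floor((p[:, 0] - tile_px / 2.0) / tile_px), 0, ntx - 2).astype(int)
    gy = np.clip(np.floor((p[:, 1] - tile_px / 2.0) / tile_px), 0, nty - 2).astype(int)
    new = np.zeros_like(p)
    dth = np.zeros(len(p))
    wsum = np.zeros(len(p))
    exact = np.full(len(p), -1, dtype=int)
    parts = []
    for dy in (0, 1):
        for dx in (0, 1):
            ts = tile_grid[gy + dy, gx + dx]
            cx = (gx + dx) * tile_px + tile_px / 2.0
            cy = (gy + dy) * tile_px + tile_px / 2.0
            d2 = (p[:, 0] - cx)**2 + (p[:, 1] - cy)**2
            parts.append((ts, d2))
    hit = np.zeros(len(p), dtype=bool)
    for k, (ts, d2) in enumerate(parts):
        on_centre = d2 < 1e-18
        hit |= on_centre
        exact[on_centre] = k
    for k, (ts, d2) in enumerate(parts):
        w = np.where(hit, (exact == k).astype(float), 1.0 / np.maximum(d2, 1e-18))
        tpts = np.empty_like(p)
        theta_i = np.empty(len(p))
        # group identical transforms for vectorization
        uniq: dict = {}
        for i, tt in enumerate(ts):
            uniq.setdefault(id(tt), (tt, []))[1].append(i)
        for tt, idxs in uniq.values():
            idxs = np.asarray(idxs)
            tpts[idxs] = tt(p[idxs])
            theta_i[idxs] = tt.theta
        new += w[:, None] * tpts
        dth += w * theta_i
        wsum += w
    new /= wsum[:, None]
    dth /= wsum
    out["x"] = new[:, 0]
    out["y"] = new[:, 1]
    out["theta_deg"] = (nuclei.theta_deg.to_numpy(dtype=float) + dth) % 180.0
    return out


def match_score(s1: RegionalSlide, s2: RegionalSlide) -> float:
    """Relative distortion of two slides: 1 - matched / mean(non-empty).

    Pixels are matched when non-empty in both slides; the denominator is the
    mean of the two slides' non-empty pixel counts.  0 = perfectly matched.
    """
    n1 = s1.category != CAT_EMPTY
    n2 = s2.category != CAT_EMPTY
    denom = 0.5 * (n1.sum() + n2.sum())
    if denom == 0:
        return 1.0
    return float(1.0 - (n1 & n2).sum() / denom)


def _densest_substack(stack: list[RegionalSlide], length: int) -> tuple[int, int]:
    counts = np.array([s.nonempty_count() for s in stack], dtype=float)
    length = min(length, len(stack))
    means = np.convolve(counts, np.ones(length), mode="valid") / length
    start = int(np.argmax(means))
    return start, start + length


def _global_reference(stack: list[RegionalSlide], lo: int, hi: int) -> int:
    """Slide with the lowest mean match score within the densest substack.

    Ties break to the slide nearest the substack middle, then lowest index.
    """
    idxs = list(range(lo, hi))
    scores = np.zeros(len(idxs))
    for a in range(len(idxs)):
        vals = [match_score(stack[idxs[a]], stack[idxs[b]])
                for b in range(len(idxs)) if b != a]
        scores[a] = np.mean(vals) if vals else 0.0
    mid = (len(idxs) - 1) / 2.0
    order = sorted(range(len(idxs)),
                   key=lambda a: (round(scores[a], 12), abs(a - mid), a))
    return idxs[order[0]]


def order_and_register(stack: list[RegionalSlide],
                       params: ElasticParams | None = None
                       ) -> dict:
    """Reference-ordered elastic registration of a rigidly aligned stack.

    Returns a dict with the registered ``stack``, ``reference`` indices, the
    ``global_reference`` index, per-slide post-registration ``scores`` and
    boolean ``discard`` flags.
    """
    params = params or ElasticParams()
    n = len(stack)
    if n < 3:
        raise ValueError("need at least 3 slides")
    lo, hi = _densest_substack(stack, params.substack_len)
    g = _global_reference(stack, lo, hi)
    # local references outward from the global reference, one per group,
    # chosen by best match score to the previous reference
    refs = [g]
    for side in (+1, -1):
        prev = g
        pos = g + side
        while 0 <= pos < n:
            group = [i for i in range(pos, pos + side * params.ref_group, side)
                     if 0 <= i < n]
            if not group:
                break
            best = min(group, key=lambda i: (match_score(stack[i], stack[prev]), i))
            refs.append(best)
            prev = best
            pos = group[-1] + side
    refs_sorted = sorted(refs)
    out = list(stack)
    scores = [0.0] * n
    discard = [False] * n
    # register references chainwise toward the global reference
    for side in (+1, -1):
        chain = [g] + [r for r in (refs_sorted if side > 0 else refs_sorted[::-1])
                       if (r - g) * side > 0]
        last_good = g
        for r in chain[1:]:
            warped, _ = register_slide(out[r], out[last_good], params)
            sc = match_score(warped, out[last_good])
            scores[r] = sc
            if sc > params.qc_threshold:
                discard[r] = True     # re-run later refs from last good one
            else:
                out[r] = warped
                last_good = r
    good_refs = [r for r in refs_sorted if not discard[r]] or [g]
    for i in range(n):
        if i in refs_sorted:
            continue
        r = min(good_refs, key=lambda rr: (abs(rr - i), rr))
        warped, _ = register_slide(out[i], out[r], params)
        sc = match_score(warped, out[r])
        scores[i] = sc
        if sc > params.qc_threshold:
            discard[i] = True
        else:
            out[i] = warped
    return {"stack": out, "references": refs_sorted, "global_reference": g,
            "scores": scores, "discard": discard}
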