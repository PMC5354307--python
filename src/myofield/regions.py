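"""Phase II: coarse-graining nuclear orientations into regional direction pixels.

Each slide is divided into regions of 128x128 image pixels (~47.5 µm at the
0.371 µm/px protocol).  A region becomes one coarse pixel carrying a category

* ``empty``    — fewer than two smooth-muscle-sized nuclei,
* ``planar``   — fibres lying in the cut plane, with a headless direction
  theta = circular median of the nuclear angles in the region,
* ``vertical`` — fibres perpendicular to the plane, or direction too
  unreliable (circular IQR of the angles > 45 deg),

together with nuclear counts.  Nuclei with aspect ratio > 2.0 count as
planar-class, < 1.6 as vertical-class, and indeterminate nuclei in [1.6, 2.0]
count in *both* classes for the 5/9 vertical-majority rule.  Only nuclei in
the smooth-muscle size range 10–60 µm² drive category and direction; all
sizes are tallied separately for the vessel and placenta detectors.

Slides are padded with empty pixels, content centred, to a fixed 800 x 1600
frame so that registration can move tissue without leaving the canvas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import angles
from .config import NucleiParams, RegionParams, ResolutionConfig

__all__ = [
    "CAT_EMPTY", "CAT_PLANAR", "CAT_VERTICAL",
    "RegionPixel", "RegionalSlide",
    "classify_region", "nuclei_to_region_coords", "grid_from_nuclei", "pad_and_grid",
]

CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL = 0, 1, 2

#: columns of the per-slide nuclei table, in region-pixel coordinates
NUCLEI_COLUMNS = ["x", "y", "theta_deg", "aspect", "area_um2", "sm", "small"]


@dataclass
class RegionPixel:
    category: int
    theta: float | None     # deg in [0, 180); planar only
    count: float            # smooth-muscle-sized nuclei
    count_all: float = 0.0
    count_small: float = 0.0


@dataclass
class RegionalSlide:
    """Coarse-grained slide on the padded frame.

    Plane arrays are (H, W) with H rows (y) and W columns (x); ``nuclei``
    holds the individual nuclei in region-pixel coordinates so that the
    registration stages can transform them and re-derive the planes.
    """

    category: np.ndarray            # uint8, CAT_*
    theta: np.ndarray               # float64, deg; NaN where not planar
    count: np.ndarray               # float64, SM-sized nuclei (possibly averaged)
    count_all: np.ndarray
    count_small: np.ndarray
    nuclei: pd.DataFrame            # NUCLEI_COLUMNS
    slide_number: int
    pitch_um: float                 # region pitch, µm
    source_slides: tuple = ()       # filled by stack assembly
    flags: dict = field(default_factory=dict)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.category.shape

    def nonempty_count(self) -> int:
        return int((self.category != CAT_EMPTY).sum())


def classify_region(aspects, thetas, params: RegionParams | None = None,
                    count_all: float = 0.0, count_small: float = 0.0,
                    divisor: float = 1.0) -> RegionPixel:
    """Classify one region from the smooth-muscle-sized nuclei it contains."""
    params = params or RegionParams()
    aspects = np.asarray(aspects, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    n = aspects.size
    if n < params.min_count:
        return RegionPixel(CAT_EMPTY, None, n / divisor, count_all / divisor,
                           count_small / divisor)
    planar_cls = int((aspects >= params.vertical_aspect).sum())   # incl. indeterminate
    vert_cls = int((aspects <= params.planar_aspect).sum())       # incl. indeterminate
    counts = (n / divisor, count_all / divisor, count_small / divisor)
    if vert_cls / (planar_cls + vert_cls) > params.vertical_fraction:
        return RegionPixel(CAT_VERTICAL, None, *counts)
    theta = angles.circular_median(thetas)
    if angles.circular_iqr(thetas) > params.max_iqr_deg:
        return RegionPixel(CAT_VERTICAL, None, *counts)
    return RegionPixel(CAT_PLANAR, theta, *counts)


def nuclei_to_region_coords(table: pd.DataFrame, cfg: ResolutionConfig,
                            nuc: NucleiParams | None = None,
                            content_px: tuple[int, int] | None = None,
                            frame: tuple[int, int] = (1600, 800),
                            centre: bool = True) -> pd.DataFrame:
    """Convert an extracted ellipse table (image px) to region-pixel coords.

    ``content_px`` is the (height, width) of the slide image in px; if None it
    is inferred from the data extent.  The content is centred on the padded
    ``frame`` (H, W in regions); overflow raises ``frame overflow``.
    """
    nuc = nuc or NucleiParams()
    r = cfg.region_px
    if content_px is None:
        if len(table):
            content_px = (int(table.cy.max()) + 1, int(table.cx.max()) + 1)
        else:
            content_px = (r, r)
    rows = math.ceil(content_px[0] / r)
    cols = math.ceil(content_px[1] / r)
    if rows > frame[0] or cols > frame[1]:
        raise ValueError("frame overflow: content larger than padded frame")
    top = (frame[0] - rows) // 2 if centre else 0
    left = (frame[1] - cols) // 2 if centre else 0
    lo, hi = nuc.sm_area_um2
    out = pd.DataFrame({
        "x": table.cx.to_numpy(dtype=float) / r + left,
        "y": table.cy.to_numpy(dtype=float) / r + top,
        "theta_deg": table.theta_deg.to_numpy(dtype=float),
        "aspect": table.aspect.to_numpy(dtype=float),
        "area_um2": table.area_um2.to_numpy(dtype=float),
    })
    out["sm"] = (out.area_um2 >= lo) & (out.area_um2 <= hi)
    out["small"] = out.area_um2 < nuc.small_area_um2
    return out


def grid_from_nuclei(nuclei: pd.DataFrame, frame: tuple[int, int],
                     params: RegionParams | None = None,
                     divisor: float = 1.0, classify: bool = True) -> dict:
    """Re-derive the regional planes from a (possibly transformed) nuclei table.

    Each nucleus is assigned to the region containing its centre (floor
    division); nuclei that left the frame are dropped.  ``divisor`` averages
    counts over pooled source slides (Phase IV).  ``classify=False`` skips
    the per-region direction statistics and only tallies counts (every region
    with enough nuclei marked planar without an angle) — a fast path for
    count-driven stages.
    """
    params = params or RegionParams()
    h, w = frame
    category = np.zeros(frame, dtype=np.uint8)
    theta = np.full(frame, np.nan, dtype=np.float64)
    count = np.zeros(frame, dtype=np.float64)
    count_all = np.zeros(frame, dtype=np.float64)
    count_small = np.zeros(frame, dtype=np.float64)
    if len(nuclei) and not classify:
        ix = np.floor(nuclei.x.to_numpy(dtype=float)).astype(np.int64)
        iy = np.floor(nuclei.y.to_numpy(dtype=float)).astype(np.int64)
        ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        flat = iy[ok] * w + ix[ok]
        sm = nuclei.sm.to_numpy()[ok]
        small = nuclei.small.to_numpy()[ok]
        np.add.at(count.reshape(-1), flat[sm], 1.0 / divisor)
        np.add.at(count_all.reshape(-1), flat, 1.0 / divisor)
        np.add.at(count_small.reshape(-1), flat[small], 1.0 / divisor)
        category[count * divisor >= params.min_count] = CAT_PLANAR
    elif len(nuclei):
        ix = np.floor(nuclei.x.to_numpy(dtype=float)).astype(np.int64)
        iy = np.floor(nuclei.y.to_numpy(dtype=float)).astype(np.int64)
        ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        idx = iy[ok] * w + ix[ok]
        sm = nuclei.sm.to_numpy()[ok]
        small = nuclei.small.to_numpy()[ok]
        asp = nuclei.aspect.to_numpy(dtype=float)[ok]
        th = nuclei.theta_deg.to_numpy(dtype=float)[ok]
        order = np.argsort(idx, kind="stable")
        idx, sm, small = idx[order], sm[order], small[order]
        asp, th = asp[order], th[order]
        uniq, starts = np.unique(idx, return_index=True)
        starts = np.append(starts, len(idx))
        for k, flat in enumerate(uniq):
            s, e = starts[k], starts[k + 1]
            a = asp[s:e][sm[s:e]]
            t = th[s:e][sm[s:e]]
            px = classify_region(a, t, params,
                                 count_all=e - s,
                                 count_small=float(small[s:e].sum()),
                                 divisor=divisor)
            r, c = divmod(int(flat), w)
            category[r, c] = px.category
            count[r, c] = px.count
            count_all[r, c] = px.count_all
            count_small[r, c] = px.count_small
            if px.theta is not None:
                theta[r, c] = px.theta
    return {"category": category, "theta": theta, "count": count,
            "count_all": count_all, "count_small": count_small}


def pad_and_grid(table: pd.DataFrame, cfg: ResolutionConfig,
                 slide_number: int = 0,
                 nuc: NucleiParams | None = None,
                 params: RegionParams | None = None,
                 content_px: tuple[int, int] | None = None) -> RegionalSlide:
    """Build a padded RegionalSlide from an extracted ellipse table (image px)."""
    params = params or RegionParams()
    frame = (params.frame_h, params.frame_w)
    nuclei = nuclei_to_region_coords(table, cfg, nuc, content_px, frame)
    planes = grid_from_nuclei(nuclei, frame, params)
    return RegionalSlide(nuclei=nuclei, slide_number=slide_number,
                         pitch_um=cfg.pitch_um, **planes)


def rebuild(slide: RegionalSlide, nuclei: pd.DataFrame | None = None,
            divisor: float = 1.0) -> RegionalSlide:
    """Slide with planes re-derived from (new) nuclei; metadata preserved."""
    nuclei = slide.nuclei if nuclei is None else nuclei
    planes = grid_from_nuclei(nuclei, slide.frame_shape, divisor=divisor,
                              classify=not slide.flags.get("counts_only", False))
    return RegionalSlide(nuclei=nuclei, slide_number=slide.slide_number,
                         pitch_um=slide.pitch_um, source_slides=slide.source_slides,
                         flags=dict(slide.flags), **planes)
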