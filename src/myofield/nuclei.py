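"""Phase I: nuclear ellipse extraction from RGB histology tiles.

H&E staining renders nuclei purple on a pink cytoplasm background, so nuclei
are isolated by *local* colour thresholding: the tile is divided into
non-overlapping 32x32 px windows and a pixel is foreground iff its red value
falls below 5/6 of the window's mean red AND its blue value falls below the
window's mean blue.  Connected components of the binary mask are then fitted
with second-moment ellipses (major-axis orientation from the image moments,
minor axis fixed so that the ellipse area equals the component area — the
standard particle-analysis convention) and filtered by size.

Conventions: coordinates are 0-based with origin at the top-left, x rightward
and y downward; angles are the major-axis angle from the +x axis in [0, 180),
measured counter-clockwise in (x, -y), i.e. visually clockwise on screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import NucleiParams, ResolutionConfig

__all__ = ["EllipseRecord", "local_threshold", "fit_ellipses", "extract_tile"]

ELLIPSE_COLUMNS = ["cx", "cy", "area_px", "area_um2", "aspect", "theta_deg", "size_class"]


@dataclass
class EllipseRecord:
    """One fitted nuclear ellipse."""

    cx: float           # px, tile-global
    cy: float
    area_px: float
    area_um2: float
    aspect: float       # major / minor, >= 1
    theta_deg: float    # major-axis angle from +x, [0, 180)
    size_class: str     # 'primary' | 'small' | 'large'


def _window_means(channel: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel window mean: each pixel gets the mean of its 32x32 window.

    Windows tile the image without overlap; partial windows at the image
    border keep their own mean (no mirroring).
    """
    h, w = channel.shape
    ye = np.arange(0, h, window)
    xe = np.arange(0, w, window)
    sums = np.add.reduceat(np.add.reduceat(channel.astype(np.float64), ye, axis=0), xe, axis=1)
    hh = np.diff(np.append(ye, h))
    ww = np.diff(np.append(xe, w))
    means = sums / (hh[:, None] * ww[None, :])
    return np.repeat(np.repeat(means, hh, axis=0), ww, axis=1)


def local_threshold(tile: np.ndarray, cfg: ResolutionConfig,
                    params: NucleiParams | None = None) -> np.ndarray:
    """Binary nucleus mask from an 8-bit RGB tile."""
    if tile.ndim != 3 or tile.shape[2] < 3:
        raise ValueError("RGB tile required")
    params = params or NucleiParams()
    red = tile[..., 0].astype(np.float64)
    blue = tile[..., 2].astype(np.float64)
    mr = _window_means(red, cfg.window_px)
    mb = _window_means(blue, cfg.window_px)
    return (red < params.red_factor * mr) & (blue < params.blue_factor * mb)


def _moment_ellipse(ys: np.ndarray, xs: np.ndarray) -> tuple:
    """Second-moment ellipse of a pixel set: (cx, cy, aspect, theta_deg).

    A 1/12 px^2 term (the second moment of a unit pixel) regularizes the
    covariance so single-row components keep a finite aspect ratio.
    """
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = -(ys - cy)          # y-up frame for the angle convention
    cxx = (dx**2).mean() + 1.0 / 12.0
    cyy = (dy**2).mean() + 1.0 / 12.0
    cxy = (dx * dy).mean()
    t = 0.5 * (cxx + cyy)
    d = np.sqrt((0.5 * (cxx - cyy)) ** 2 + cxy**2)
    l1, l2 = t + d, max(t - d, 1e-12)
    theta = np.rad2deg(0.5 * np.arctan2(2.0 * cxy, cxx - cyy)) % 180.0
    return cx, cy, float(np.sqrt(l1 / l2)), float(theta)


def fit_ellipses(mask: np.ndarray, cfg: ResolutionConfig,
                 params: NucleiParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit ellipses to 8-connected components of a binary mask.

    Returns ``(primary, all_sizes)``: the primary table keeps components with
    40 px <= area <= 600 px; the all-sizes table additionally retains smaller
    (noise / red-blood-cell) and larger (cluster) components, flagged by
    ``size_class``, for the downstream vessel and placenta detectors.
    """
    params = params or NucleiParams()
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    px_area = cfg.um_per_px_x * cfg.um_per_px_y
    rows = []
    if n:
        objs = ndimage.find_objects(labels)
        for i, sl in enumerate(objs, start=1):
            ys, xs = np.nonzero(labels[sl] == i)
            ys = ys + sl[0].start
            xs = xs + sl[1].start
            area = float(len(xs))
            cx, cy, aspect, theta = _moment_ellipse(ys, xs)
            if area < params.min_area_px:
                cls = "small"
            elif area > params.max_area_px:
                cls = "large"
            else:
                cls = "primary"
            rows.append((cx, cy, area, area * px_area, aspect, theta, cls))
    all_sizes = pd.DataFrame(rows, columns=ELLIPSE_COLUMNS)
    primary = all_sizes[all_sizes.size_class == "primary"].reset_index(drop=True)
    return primary, all_sizes


def extract_tile(tile: np.ndarray, cfg: ResolutionConfig,
                 params: NucleiParams | None = None,
                 offset_px: tuple[float, float] = (0.0, 0.0)) -> pd.DataFrame:
    """Threshold + fit one tile; returns the all-sizes table in global px."""
    params = params or NucleiParams()
    mask = local_threshold(tile, cfg, params)
    _, table = fit_ellipses(mask, cfg, params)
    table = table.copy()
    table["cx"] += offset_px[0]
    table["cy"] += offset_px[1]
    return table
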