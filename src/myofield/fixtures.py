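"""Synthetic slides, stacks, and phantom volumes with known ground truth.

Real myometrial blocks are not distributable, so the test surface of the
package is built on synthetic data that emulates the features the pipeline
keys on:

* elliptical nuclei whose in-plane orientation follows a prescribed
  direction field plus angular noise, drawn dark purple on a pink background
  (near-circular footprints where the field leaves the plane);
* bundle boundaries as low-density gaps, red-blood-cell-sized objects, and
  dense placenta-like patches;
* per-slide rigid motions and smooth, low-frequency elastic distortions with
  exactly recorded inverse ground truth;
* analytic phantom volumes (slabs, layered slabs, cylinders, inclined
  sheets) with known direction fields, bundle labels and widths.

Everything is driven by :class:`numpy.random.Generator` seeded from the spec,
so identical specs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .config import DensityParams, NucleiParams, RegionParams, ResolutionConfig
from .regions import (CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL, RegionalSlide,
                      grid_from_nuclei)

__all__ = [
    "PhantomSpec", "render_slide", "synth_nuclei", "synth_regional_slide",
    "ElasticWarp", "distort_stack", "PhantomVolume", "phantom_volume",
    "patch_field", "stereology_sample",
]

# synthetic H&E colour model: nuclei / background RGB and pixel noise sd,
# chosen so the 5/6-red and mean-blue local thresholds separate them robustly
NUCLEUS_RGB = (90, 60, 140)
BACKGROUND_RGB = (240, 200, 210)
PIXEL_NOISE_SD = 8.0

# nucleus geometry (µm, full axes): keeps fitted areas inside the 10–60 µm²
# smooth-muscle band and aspect > 2 for in-plane nuclei
MINOR_UM = (4.2, 5.2)
MAJOR_UM = (10.5, 13.5)
RBC_UM = (2.6, 3.4)


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic slide.

    ``theta``/``phi`` give the headless fibre direction per region (planar
    angle in [0, 180) and elevation from the slide plane in [-90, 90]);
    densities are nuclei per region.  ``seed`` fixes all randomness.
    """

    theta: np.ndarray                    # (ny, nx) deg
    phi: Optional[np.ndarray] = None     # (ny, nx) deg; None: all in-plane
    nuclear_density: float = 8.0
    angle_noise_sd: float = 5.0
    bundle_mask: Optional[np.ndarray] = None       # bool; False: gap
    rbc_density: float = 0.0
    dense_patch_mask: Optional[np.ndarray] = None  # bool; placenta-like
    dense_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float) % 180.0
        if self.phi is None:
            self.phi = np.zeros_like(self.theta)
        if self.bundle_mask is None:
            self.bundle_mask = np.ones(self.theta.shape, dtype=bool)
        if self.nuclear_density < 0 or self.rbc_density < 0:
            raise ValueError("density must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


def _sample_nuclei(spec: PhantomSpec, tile_px: int, cfg: ResolutionConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw ground-truth nuclei (image-px coordinates) for every region."""
    ny, nx = spec.shape
    upx = cfg.um_per_px_x
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            dens = spec.nuclear_density if spec.bundle_mask[iy, ix] else 0.0
            if spec.dense_patch_mask is not None and spec.dense_patch_mask[iy, ix]:
                dens *= spec.dense_factor
            n = rng.poisson(dens)
            n_rbc = rng.poisson(spec.rbc_density) if spec.bundle_mask[iy, ix] else 0
            phi = float(spec.phi[iy, ix])
            th0 = float(spec.theta[iy, ix])
            for _ in range(n):
                minor = rng.uniform(*MINOR_UM)
                major = rng.uniform(*MAJOR_UM)
                # footprint of a tilted nucleus: apparent major axis shrinks
                app_major = max(minor, major * np.sqrt(
                    np.cos(np.deg2rad(phi))**2
                    + (minor / major)**2 * np.sin(np.deg2rad(phi))**2))
                theta = (th0 + rng.normal(0.0, spec.angle_noise_sd)) % 180.0
                rows.append((
                    (ix + rng.uniform(0.04, 0.96)) * tile_px,
                    (iy + rng.uniform(0.04, 0.96)) * tile_px,
                    app_major / upx, minor / upx, theta, False))
            for _ in range(n_rbc):
                d = rng.uniform(*RBC_UM)
                rows.append((
                    (ix + rng.uniform(0.04, 0.96)) * tile_px,
                    (iy + rng.uniform(0.04, 0.96)) * tile_px,
                    d * rng.uniform(1.0, 1.3) / upx, d / upx,
                    rng.uniform(0.0, 180.0), True))
    df = pd.DataFrame(rows, columns=["cx", "cy", "major_px", "minor_px",
                                     "theta_deg", "is_rbc"])
    df["area_um2"] = np.pi / 4.0 * df.major_px * df.minor_px * upx * cfg.um_per_px_y
    df["aspect"] = df.major_px / df.minor_px
    return df


def render_slide(spec: PhantomSpec, tile_px: int = 128,
                 cfg: ResolutionConfig | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic H&E slide; returns (RGB uint8 image, ground truth).

    Nuclei are filled ellipses with major axis along the local field
    direction plus Normal(0, angle_noise_sd) noise; regions where the field
    is steeply out of plane get near-circular footprints.  The ground-truth
    table lists every rendered nucleus with exact parameters.
    """
    if tile_px < 64:
        raise ValueError("tile_px must be >= 64")
    cfg = cfg or ResolutionConfig()
    mean_area_px = np.pi / 4.0 * np.mean(MAJOR_UM) * np.mean(MINOR_UM) \
        / (cfg.um_per_px_x * cfg.um_per_px_y)
    peak = spec.nuclear_density * (spec.dense_factor if spec.dense_patch_mask
                                   is not None else 1.0)
    if peak * mean_area_px > 0.45 * tile_px**2:
        raise ValueError("infeasible density: nuclei cannot be packed")
    rng = np.random.default_rng(spec.seed)
    truth = _sample_nuclei(spec, tile_px, cfg, rng)
    ny, nx = spec.shape
    shape = (ny * tile_px, nx * tile_px)
    img = np.empty(shape + (3,), dtype=np.float64)
    img[:] = BACKGROUND_RGB
    for row in truth.itertuples():
        # skimage.draw.ellipse rotation is measured in (row, col) space;
        # with x along columns and y down, rotation = +theta draws the major
        # axis at our theta convention (CCW in x,-y).
        rr, cc = draw_ellipse(row.cy, row.cx, row.minor_px / 2.0,
                              row.major_px / 2.0,
                              shape=shape,
                              rotation=np.deg2rad(row.theta_deg))
        img[rr, cc] = NUCLEUS_RGB
    img += rng.normal(0.0, PIXEL_NOISE_SD, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), truth


def synth_nuclei(spec: PhantomSpec, tile_px: int = 128,
                 cfg: ResolutionConfig | None = None) -> pd.DataFrame:
    """Ground-truth nuclei table only (no rendering); image-px coordinates."""
    cfg = cfg or ResolutionConfig()
    rng = np.random.default_rng(spec.seed)
    return _sample_nuclei(spec, tile_px, cfg, rng)


def synth_regional_slide(spec: PhantomSpec, slide_number: int = 0,
                         cfg: ResolutionConfig | None = None,
                         params: RegionParams | None = None,
                         frame: tuple[int, int] | None = None,
                         classify: bool = True) -> RegionalSlide:
    """Regional slide built directly from ground-truth nuclei.

    Bypasses rendering and Phase-I extraction: the ground-truth ellipse table
    is centred on the padded frame and coarse-grained exactly as measured
    nuclei would be.  Used as the fast input for registration-scale fixtures.
    """
    cfg = cfg or ResolutionConfig()
    params = params or RegionParams()
    frame = frame or (params.frame_h, params.frame_w)
    nuc = NucleiParams()
    t = synth_nuclei(spec, cfg.region_px, cfg)
    ny, nx = spec.shape
    top = (frame[0] - ny) // 2
    left = (frame[1] - nx) // 2
    if top < 0 or left < 0:
        raise ValueError("frame overflow: content larger than padded frame")
    lo, hi = nuc.sm_area_um2
    nuclei = pd.DataFrame({
        "x": t.cx.to_numpy() / cfg.region_px + left,
        "y": t.cy.to_numpy() / cfg.region_px + top,
        "theta_deg": t.theta_deg.to_numpy(),
        "aspect": t.aspect.to_numpy(),
        "area_um2": t.area_um2.to_numpy(),
    })
    nuclei["sm"] = (nuclei.area_um2 >= lo) & (nuclei.area_um2 <= hi)
    nuclei["small"] = nuclei.area_um2 < nuc.small_area_um2
    planes = grid_from_nuclei(nuclei, frame, params, classify=classify)
    return RegionalSlide(nuclei=nuclei, slide_number=slide_number,
                         pitch_um=cfg.pitch_um,
                         flags={} if classify else {"counts_only": True},
                         **planes)


def blob_mask(shape: tuple[int, int], seed: int = 0, n_holes: int = 1,
              fill: float = 0.8) -> np.ndarray:
    """Contiguous tissue-cross-section-like mask with a smooth outline.

    An ellipse filling ``fill`` of the frame, its radius perturbed by a
    low-order Fourier series, with a few interior holes — the silhouette the
    Canny edge image of a real section is dominated by.
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ang = np.arctan2(yy - cy, xx - cx)
    r = np.hypot((yy - cy) / (fill * ny / 2.0), (xx - cx) / (fill * nx / 2.0))
    pert = np.zeros_like(ang)
    for k in range(2, 6):
        pert += rng.uniform(0, 0.08) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
    mask = r <= 1.0 + pert
    for _ in range(n_holes):
        hy = rng.uniform(0.3, 0.7) * ny
        hx = rng.uniform(0.3, 0.7) * nx
        hr = rng.uniform(0.06, 0.12) * min(ny, nx)
        mask &= (yy - hy)**2 + (xx - hx)**2 > hr**2
    return mask


def patch_field(shape: tuple[int, int], n_patches: int = 12, seed: int = 0,
                gap: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Heterogeneous piecewise-constant direction field with bundle gaps.

    Regions take the angle of their nearest of ``n_patches`` random seed
    points (a Voronoi mosaic of fascicles); one-region-wide gaps are carved
    along patch boundaries so the nuclear-density image has internal edges.
    Returns ``(theta, bundle_mask)``.
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, size=(n_patches, 2)) * [ny, nx]
    ang = rng.uniform(0.0, 180.0, size=n_patches)
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy[..., None] - pts[:, 0])**2 + (xx[..., None] - pts[:, 1])**2
    lab = np.argmin(d2, axis=-1)
    theta = ang[lab]
    mask = np.ones(shape, dtype=bool)
    if gap:
        edge = np.zeros(shape, dtype=bool)
        edge[:, 1:] |= lab[:, 1:] != lab[:, :-1]
        edge[1:, :] |= lab[1:, :] != lab[:-1, :]
        mask &= ~edge
    return theta, mask


class ElasticWarp:
    """Smooth low-frequency displacement field: a sum of <= 5 Gaussian bumps.

    d(p) = sum_k a_k u_k exp(-|p - mu_k|^2 / (2 s_k^2)), rescaled so that
    max |d| over the content equals ``amplitude``; smooth (C-infinity) and
    invertible at the amplitudes used (|grad d| << 1).
    """

    def __init__(self, amplitude: float, bbox: tuple, rng: np.random.Generator,
                 n_bumps: int = 5):
        n_bumps = min(n_bumps, 5)
        (y0, y1), (x0, x1) = bbox
        self.centres = np.column_stack([
            rng.uniform(x0, x1, n_bumps), rng.uniform(y0, y1, n_bumps)])
        self.widths = rng.uniform(0.25, 0.5, n_bumps) * max(y1 - y0, x1 - x0, 1.0)
        ang = rng.uniform(0, 2 * np.pi, n_bumps)
        amp = rng.uniform(0.5, 1.0, n_bumps)
        self.vec = np.column_stack([np.cos(ang), np.sin(ang)]) * amp[:, None]
        self.amplitude = float(amplitude)
        if amplitude > 0:
            yy = np.linspace(y0, y1, 41)
            xx = np.linspace(x0, x1, 41)
            g = np.stack(np.meshgrid(xx, yy), axis=-1).reshape(-1, 2)
            m = np.linalg.norm(self._raw(g), axis=1).max()
            self.scale = amplitude / m if m > 0 else 0.0
        else:
            self.scale = 0.0

    def _raw(self, pts: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - self.centres[None, :, :])**2).sum(-1)
        w = np.exp(-d2 / (2.0 * self.widths[None, :]**2))
        return w @ self.vec

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Displacement (dx, dy) at points (x, y)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.scale * self._raw(pts)


def _rigid_apply(x, y, theta_deg, t, centre):
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    dx, dy = x - centre[0], y - centre[1]
    return (c * dx - s * dy + centre[0] + t[0],
            s * dx + c * dy + centre[1] + t[1])


def distort_stack(slides: list, rigid: list | None = None,
                  elastic_amplitude: float = 0.0, seed: int = 0,
                  n_bumps: int = 5) -> tuple[list, list]:
    """Independently distort each RegionalSlide; store exact ground truth.

    ``rigid`` is a per-slide list of ``(theta_deg, (tx, ty))`` applied about
    the frame centre (region-pixel units); the elastic part is a smooth
    Gaussian-bump field of the given maximum amplitude.  Returns the
    distorted stack and a list of ground-truth dicts with keys ``theta``,
    ``t``, ``centre`` and ``warp`` (an :class:`ElasticWarp`).
    """
    from .regions import rebuild  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    rigid = rigid or [(0.0, (0.0, 0.0))] * len(slides)
    out, truths = [], []
    for slide, (theta, t) in zip(slides, rigid):
        h, w = slide.frame_shape
        centre = ((w - 1) / 2.0, (h - 1) / 2.0)
        nuc = slide.nuclei
        if len(nuc):
            bx = (nuc.y.min(), nuc.y.max()), (nuc.x.min(), nuc.x.max())
            margin = min(nuc.x.min(), nuc.y.min(),
                         w - 1 - nuc.x.max(), h - 1 - nuc.y.max())
        else:
            bx = ((0, h - 1.0), (0, w - 1.0))
            margin = min(h, w) / 2.0
        if elastic_amplitude > margin / 2.0:
            raise ValueError("warp amplitude exceeds half the padded margin")
        warp = ElasticWarp(elastic_amplitude, bx, rng, n_bumps)
        x, y = _rigid_apply(nuc.x.to_numpy(), nuc.y.to_numpy(), theta, t, centre)
        d = warp(np.column_stack([x, y])) if len(nuc) else np.zeros((0, 2))
        new = nuc.copy()
        new["x"] = x + d[:, 0]
        new["y"] = y + d[:, 1]
        new["theta_deg"] = (nuc.theta_deg.to_numpy() + theta) % 180.0
        out.append(rebuild(slide, new))
        truths.append({"theta": float(theta), "t": (float(t[0]), float(t[1])),
                       "centre": centre, "warp": warp})
    return out, truths


# ---------------------------------------------------------------------------
# phantom volumes

@dataclass
class PhantomVolume:
    """Analytic direction volume with ground truth.

    ``category``/``theta``/``count`` mimic the regional representation that
    Phase V consumes; ``vec`` is the true headless unit direction field,
    ``labels`` the true bundle labels (0 = background) and ``widths_um`` the
    analytic bundle width per label.
    """

    category: np.ndarray        # (Z, H, W) uint8
    theta: np.ndarray           # planar angle, deg; NaN elsewhere
    count: np.ndarray           # mean cross-sectional nuclei per voxel
    vec: np.ndarray             # (Z, H, W, 3) unit vectors (x, y, z), 0 outside
    weight: np.ndarray          # 1.0 where tissue
    labels: np.ndarray          # int
    widths_um: dict
    pitch_um: float


def phantom_volume(geometry: str, dims: tuple[int, int, int],
                   bundle_width_vox: float = 10.0, seed: int = 0,
                   angle_deg: float = 90.0, elevation_deg: float = 45.0,
                   count: float = 8.0, pitch_um: float = 47.5) -> PhantomVolume:
    """Build an analytic phantom: two_layer | crossing_slabs | cylinder | slab
    | inclined_slab."""
    dims = tuple(int(d) for d in dims)
    if min(dims) < 16:
        raise ValueError("dims must each be >= 16 voxels")
    if bundle_width_vox < 2:
        raise ValueError("unresolvable: bundle width below 2 voxels")
    nz, ny, nx = dims
    category = np.zeros(dims, dtype=np.uint8)
    theta = np.full(dims, np.nan, dtype=np.float64)
    vec = np.zeros(dims + (3,), dtype=np.float64)
    labels = np.zeros(dims, dtype=np.int32)
    widths: dict = {}
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]

    def set_planar(mask, ang, label):
        category[mask] = CAT_PLANAR
        theta[mask] = ang
        vec[mask] = (np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang)), 0.0)
        labels[mask] = label

    if geometry in ("two_layer", "crossing_slabs"):
        second = angle_deg if geometry == "crossing_slabs" else 90.0
        lower = zz < nz // 2
        set_planar(lower, 0.0, 1)
        set_planar(~lower, second % 180.0, 2)
        widths = {1: (nz // 2) * pitch_um, 2: (nz - nz // 2) * pitch_um}
    elif geometry == "cylinder":
        r = bundle_width_vox / 2.0
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        inside = (yy - cy)**2 + (xx - cx)**2 <= r**2
        category[inside] = CAT_VERTICAL
        vec[inside] = (0.0, 0.0, 1.0)
        labels[inside] = 1
        widths = {1: 2.0 * r * pitch_um}
    elif geometry == "slab":
        cy = (ny - 1) / 2.0
        inside = np.abs(yy - cy) < bundle_width_vox / 2.0
        set_planar(inside, 0.0, 1)
        widths = {1: bundle_width_vox * pitch_um}
    elif geometry == "inclined_slab":
        ph = np.deg2rad(elevation_deg)
        cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
        dist = -np.sin(ph) * (xx - cx) + np.cos(ph) * (zz - cz)
        inside = np.abs(dist) < bundle_width_vox / 2.0
        category[inside] = CAT_PLANAR
        theta[inside] = 0.0
        vec[inside] = (np.cos(ph), 0.0, np.sin(ph))
        labels[inside] = 1
        widths = {1: bundle_width_vox * pitch_um}
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    tissue = category != CAT_EMPTY
    return PhantomVolume(category=category, theta=theta,
                         count=np.where(tissue, count, 0.0),
                         vec=vec, weight=tissue.astype(np.float64),
                         labels=labels, widths_um=widths, pitch_um=pitch_um)


def stereology_sample(n_nuclei: int, phi_deg: float,
                      params: DensityParams | None = None,
                      n_planes: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo mean in-plane count for a voxel holding ``n_nuclei``.

    Nuclei at elevation phi are placed at uniform random heights in a voxel
    of unit length (periodic in z); their vertical extent follows the
    projected-height model h(phi) = max(r_M sin phi, r_m).  Random section
    planes are drawn and the mean number of intersected nuclei returned —
    the quantity the stereological correction inverts.
    """
    params = params or DensityParams()
    rng = np.random.default_rng(seed)
    h = max(params.rM_over_l * abs(np.sin(np.deg2rad(phi_deg))), params.rm_over_l)
    z0 = rng.uniform(0.0, 1.0, size=n_nuclei)
    planes = rng.uniform(0.0, 1.0, size=n_planes)
    d = np.abs(z0[None, :] - planes[:, None])
    d = np.minimum(d, 1.0 - d)            # periodic column
    return float((d < h / 2.0).sum(axis=1).mean())
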