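"""Phase VIII: suppressing non-myometrial tissue.

Vasculature: red blood cells (objects below 14 µm²) are detected by the same
nuclear extraction but filtered out of the smooth-muscle range; the fraction
of RBC-sized objects per voxel is Gaussian-smoothed, thresholded, and
26-connected clusters of at least 9 voxels — filled vessel lumina — are kept
and dilated by one voxel to include the vessel wall.

Placenta (pregnant rat blocks): placental tissue is far denser in nuclei
than myometrium, so the all-sizes nuclear density (per mm²) is thresholded
at 4500 /mm², smoothed with a wide Gaussian (sigma 4 voxels), hysteresis-
thresholded (keep connected sets >= 0.3 touching >= 0.6), and clusters of at
least 10000 voxels are kept.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PlacentaParams, VesselParams
from .segmentation import smooth

__all__ = ["detect_vessels", "detect_placenta"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def detect_vessels(count_small: np.ndarray, count_all: np.ndarray,
                   params: VesselParams | None = None) -> np.ndarray:
    """Vessel mask from the per-voxel fraction of RBC-sized objects."""
    params = params or VesselParams()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(count_all > 0, count_small / np.maximum(count_all, 1e-12), 0.0)
    sm = smooth(frac, float(np.sqrt(params.gaussian_var)))
    binary = sm > params.fraction_threshold
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= params.min_vessel_voxels
        binary = keep[labels]
    else:
        binary = np.zeros_like(binary)
    return ndimage.binary_dilation(binary, structure=_STRUCT26)


def detect_placenta(count_all: np.ndarray, pitch_um: float,
                    params: PlacentaParams | None = None) -> np.ndarray:
    """Placenta mask from extended nuclear density with hysteresis."""
    params = params or PlacentaParams()
    area_mm2 = (pitch_um / 1000.0) ** 2
    density = count_all / area_mm2
    binary = (density >= params.min_density_per_mm2).astype(np.float64)
    sm = smooth(binary, params.gaussian_sigma)
    low = sm >= params.lower_threshold
    high = sm >= params.upper_threshold
    labels, n = ndimage.label(low, structure=_STRUCT26)
    if not n:
        return np.zeros_like(low)
    touching = np.unique(labels[high])
    keep = np.zeros(n + 1, dtype=bool)
    keep[touching[touching > 0]] = True
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep &= sizes >= params.min_cluster_voxels
    return keep[labels]
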