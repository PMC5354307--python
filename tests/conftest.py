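"""Shared helpers: synthetic slides, brute-force oracles, angle utilities."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from myofield.config import ResolutionConfig
from myofield.regions import NUCLEI_COLUMNS, RegionalSlide, grid_from_nuclei
from myofield.segmentation import gaussian_kernel1d


def counts_slide(mask: np.ndarray, density: float, seed: int,
                 frame: tuple[int, int] = (1600, 800), num: int = 0
                 ) -> RegionalSlide:
    """Count-driven slide: Poisson nuclei on a mask, no angle classification.

    The registration stages only consume occupancy (the edge image and the
    non-empty category plane), so a counts-only slide exercises them at full
    fidelity without the cost of per-region angle statistics.
    """
    ny, nx = mask.shape
    rng = np.random.default_rng(seed)
    n = rng.poisson(density, size=mask.shape)
    n[~mask] = 0
    tot = int(n.sum())
    iy, ix = np.nonzero(n)
    reps = n[iy, ix]
    ys = np.repeat(iy, reps) + rng.uniform(0.02, 0.98, tot)
    xs = np.repeat(ix, reps) + rng.uniform(0.02, 0.98, tot)
    top = (frame[0] - ny) // 2
    left = (frame[1] - nx) // 2
    nuc = pd.DataFrame({
        "x": xs + left, "y": ys + top,
        "theta_deg": rng.uniform(0, 180, tot),
        "aspect": np.full(tot, 2.5),
        "area_um2": np.full(tot, 30.0),
        "sm": np.ones(tot, dtype=bool),
        "small": np.zeros(tot, dtype=bool)})
    planes = grid_from_nuclei(nuc, frame, classify=False)
    return RegionalSlide(nuclei=nuc, slide_number=num,
                         pitch_um=ResolutionConfig().pitch_um,
                         flags={"counts_only": True}, **planes)


def planes_slide(category: np.ndarray, theta: np.ndarray, count: np.ndarray
                 ) -> RegionalSlide:
    """Slide shim built directly from plane arrays (no nuclei)."""
    return RegionalSlide(category=category.astype(np.uint8), theta=theta,
                         count=count, count_all=count.copy(),
                         count_small=np.zeros_like(count),
                         nuclei=pd.DataFrame(columns=NUCLEI_COLUMNS),
                         slide_number=0,
                         pitch_um=ResolutionConfig().pitch_um)


def headless_err_deg(vec: np.ndarray, true_vec: np.ndarray) -> np.ndarray:
    """Angle between headless unit vectors, in degrees."""
    dot = np.abs((vec * true_vec).sum(-1)).clip(0.0, 1.0)
    return np.degrees(np.arccos(dot))


# ---------------------------------------------------------------------------
# brute-force double-sum oracles for the anisotropy / merge closed forms
#
# The truncated, renormalized Gaussian with zero padding is a linear map
# K[p, j] = prod_d g1[p_d - j_d] over flattened indices; the weighted
# anisotropy and the pool-comparison function are then quadratic forms whose
# coefficient matrices follow directly from their defining double sums:
#
#   I_w(p)    = sum_jk K[p,j] K[p,k] w_j w_k (2 (v_j . v_k)^2 - 1)
#   f(p, q)   = sum_jk K[p,j] K[q,k] w_j w_k (v_j . v_k)^2
#               / ((K w)(p) (K w)(q))
#
# identically in two dimensions (unit in-plane vectors) and three.


def kernel_matrix(shape: tuple, sigma: float, truncate: float = 3.0
                  ) -> np.ndarray:
    g1 = gaussian_kernel1d(sigma, truncate)
    t = (len(g1) - 1) // 2
    n = int(np.prod(shape))
    idx = np.array(list(itertools.product(*[range(s) for s in shape])))
    K = np.ones((n, n))
    for d in range(len(shape)):
        diff = idx[:, None, d] - idx[None, :, d]
        vals = np.where(np.abs(diff) <= t, g1[np.clip(diff + t, 0, 2 * t)], 0.0)
        K *= vals
    return K


def brute_iw(K: np.ndarray, vecs: np.ndarray, w: np.ndarray) -> np.ndarray:
    """I_w at every point from the defining double sum."""
    dots2 = (vecs @ vecs.T) ** 2
    C = np.outer(w, w) * (2.0 * dots2 - 1.0)
    return np.einsum("pj,jk,pk->p", K, C, K)


def brute_f(K: np.ndarray, vecs: np.ndarray, w: np.ndarray) -> np.ndarray:
    """f(p, q) for all point pairs from the defining double sum."""
    dots2 = (vecs @ vecs.T) ** 2
    C = np.outer(w, w) * dots2
    kw = K @ w
    return (K @ C @ K.T) / np.outer(kw, kw)


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)
    return make
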