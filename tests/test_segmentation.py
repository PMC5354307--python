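import numpy as np
import pytest
from scipy import ndimage

from myofield import fixtures, segmentation
from myofield.config import Seg2DParams, Seg3DParams
from tests.conftest import planes_slide


def test_gaussian_kernel_normalized_and_symmetric():
    for s in (0.4, 1.0, 2.7):
        g = segmentation.gaussian_kernel1d(s)
        assert g.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g, g[::-1])
        assert len(g) % 2 == 1


def test_smooth_matches_direct_convolution():
    rng = np.random.default_rng(1)
    arr = rng.normal(size=(12, 14))
    g = segmentation.gaussian_kernel1d(1.3)
    ref = ndimage.convolve1d(ndimage.convolve1d(
        arr, g, axis=0, mode="constant"), g, axis=1, mode="constant")
    np.testing.assert_allclose(segmentation.smooth(arr, 1.3), ref, atol=1e-12)


def test_watershed_merge_two_basins():
    # two aligned plateaus separated by a low saddle, f below f_min: the
    # saddle becomes watershed (-1) and two pools remain
    values = np.array([[5.0, 4.0, 0.1, 4.0, 5.0]])
    allowed = np.ones_like(values, dtype=bool)
    labels = segmentation.watershed_merge(values, allowed,
                                          lambda a, b: 0.0, 0.5)
    assert labels.max() == 2
    assert (labels == -1).sum() == 1
    assert labels[0, 2] == -1


def test_watershed_merge_joins_compatible_pools():
    values = np.array([[5.0, 4.0, 0.1, 4.0, 5.0]])
    allowed = np.ones_like(values, dtype=bool)
    labels = segmentation.watershed_merge(values, allowed,
                                          lambda a, b: 1.0, 0.5)
    assert labels.max() == 1
    assert (labels == -1).sum() == 0
    assert (labels[allowed] == 1).all()


def test_watershed_merge_excluded_points():
    values = np.ones((3, 3))
    allowed = np.zeros((3, 3), dtype=bool)
    allowed[1, 1] = True
    labels = segmentation.watershed_merge(values, allowed,
                                          lambda a, b: 1.0, 0.5)
    assert labels[1, 1] == 1
    assert (labels[~allowed] == 0).all()


def _uniform_slide(theta_deg=30.0, shape=(24, 24), count=8.0):
    cat = np.ones(shape, dtype=np.uint8)
    th = np.full(shape, float(theta_deg))
    cnt = np.full(shape, count)
    return planes_slide(cat, th, cnt)


def test_grey_2d_uniform_field():
    slide = _uniform_slide()
    cached = segmentation.grey_2d(slide)
    # interior anisotropy ~ (G*W)^2 for a perfectly aligned field
    centre = cached.iw[12, 12]
    assert centre == pytest.approx(cached.gw[12, 12] ** 2, rel=1e-9)
    assert not cached.vertical_edges.any()
    f = segmentation.merge_f_2d(12 * 24 + 12, 12 * 24 + 13, cached)
    assert f == pytest.approx(1.0, rel=1e-9)


def test_merge_f_2d_perpendicular_fields():
    cat = np.ones((8, 16), dtype=np.uint8)
    th = np.where(np.arange(16)[None, :] < 8, 0.0, 90.0)
    th = np.broadcast_to(th, (8, 16)).copy()
    slide = planes_slide(cat, th, np.full((8, 16), 5.0))
    cached = segmentation.grey_2d(slide)
    f = segmentation.merge_f_2d(4 * 16 + 1, 4 * 16 + 14, cached)
    assert f == pytest.approx(0.0, abs=1e-9)
    # empty neighbourhood: f = 0 by convention
    empty = planes_slide(np.zeros((8, 8), np.uint8), np.full((8, 8), np.nan),
                         np.zeros((8, 8)))
    c2 = segmentation.grey_2d(empty)
    assert segmentation.merge_f_2d(0, 1, c2) == 0.0


def test_vertical_edges_ring_around_vertical_core():
    cat = np.ones((20, 20), dtype=np.uint8)
    cat[8:12, 8:12] = 2                   # vertical block
    th = np.where(cat == 1, 45.0, np.nan)
    cnt = np.full((20, 20), 30.0)         # strong vertical grey value
    slide = planes_slide(cat, th, cnt)
    cached = segmentation.grey_2d(slide)
    assert cached.vertical_edges.any()
    # edges lie outside the above-threshold core
    sm = segmentation.smooth(np.where(cat == 2, 30.0, 0.0), 1.0)
    assert not cached.vertical_edges[sm >= 10.0].any()


def test_segment_2d_splits_perpendicular_halves():
    cat = np.ones((16, 32), dtype=np.uint8)
    th = np.where(np.arange(32)[None, :] < 16, 10.0, 100.0)
    th = np.broadcast_to(th, (16, 32)).copy()
    slide = planes_slide(cat, th, np.full((16, 32), 6.0))
    res = segmentation.segment_2d(slide)
    labels = res["labels"]
    left = labels[8, 4]
    right = labels[8, 28]
    assert left >= 1 and right >= 1 and left != right


def test_double_angle_3d_identity():
    rng = np.random.default_rng(2)
    v = rng.normal(size=(50, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.normal(size=(50, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    dv = segmentation.double_angle_3d(v)
    du = segmentation.double_angle_3d(u)
    lhs = (dv * du).sum(axis=(-2, -1))
    rhs = 4.0 * ((v * u).sum(-1)) ** 2 - 1.0
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)
    # zero vectors stay zero
    assert not segmentation.double_angle_3d(np.zeros((2, 3))).any()


def test_grey_3d_rejects_non_unit_vectors():
    vec = np.zeros((4, 4, 4, 3))
    vec[..., 0] = 0.5
    with pytest.raises(ValueError, match="non-unit"):
        segmentation.grey_3d(vec, np.ones((4, 4, 4)))


def test_grey_3d_per_voxel_sigma_matches_scalar():
    ph = fixtures.phantom_volume("two_layer", (16, 16, 16))
    scalar = segmentation.grey_3d(ph.vec, ph.weight, 1.0)
    sig_map = np.full(ph.weight.shape, 1.0)
    mapped = segmentation.grey_3d(ph.vec, ph.weight, sig_map)
    np.testing.assert_allclose(mapped.iw, scalar.iw, atol=1e-12)
    np.testing.assert_allclose(mapped.gw, scalar.gw, atol=1e-12)


def test_adaptive_sigma_small_in_uniform_interior():
    ph = fixtures.phantom_volume("slab", (16, 24, 24), bundle_width_vox=16)
    sig = segmentation.adaptive_sigma(ph.vec, ph.weight)
    p = Seg3DParams()
    # deep inside a uniform slab there is no residual: the penalty term
    # selects the smallest scale
    assert sig[8, 11, 12] == pytest.approx(p.sigma_min)
    assert (sig >= p.sigma_min - 1e-9).all()
    assert (sig <= p.sigma_max + 1e-9).all()


def test_segment_3d_crossing_slabs():
    sep = fixtures.phantom_volume("crossing_slabs", (16, 16, 16),
                                  angle_deg=60.0)
    res = segmentation.segment_3d(sep.vec, sep.weight)
    assert res["labels"].max() == 2       # 60 deg apart: f = cos^2 60 < 0.5
    near = fixtures.phantom_volume("crossing_slabs", (16, 16, 16),
                                   angle_deg=30.0)
    res2 = segmentation.segment_3d(near.vec, near.weight)
    assert res2["labels"].max() == 1      # 30 deg apart: f = cos^2 30 > 0.5
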