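import numpy as np
import pandas as pd
import pytest

from myofield import elastic_reg, fixtures
from myofield.config import ElasticParams
from myofield.elastic_reg import TileTransform


def _mosaic_slide(seed, shape=(48, 24), n_patches=30, density=8.0):
    theta, mask = fixtures.patch_field(shape, n_patches, seed=2)
    spec = fixtures.PhantomSpec(theta=theta, bundle_mask=mask,
                                nuclear_density=density, angle_noise_sd=5.0,
                                seed=seed)
    return fixtures.synth_regional_slide(spec, slide_number=seed)


def test_tile_transform_geometry():
    tt = TileTransform(theta=90.0, t=np.array([2.0, 0.0]),
                       centre=np.array([8.0, 8.0]))
    out = tt(np.array([[9.0, 8.0]]))
    np.testing.assert_allclose(out, [[10.0, 9.0]], atol=1e-12)
    assert not tt.is_identity
    assert TileTransform(centre=np.array([0.0, 0.0])).is_identity


def test_heterogeneity_uniform_vs_mixed():
    slide = _mosaic_slide(11)
    cat = slide.category
    th = slide.theta
    rect = elastic_reg._content_bbox(slide)   # (y0, y1, x0, x1)
    h_all = elastic_reg.heterogeneity(cat, th, rect)
    one = np.full_like(th, 30.0)
    h_uni = elastic_reg.heterogeneity(cat, one, rect)
    # a single shared angle leaves only the perpendicular fill of the gaps
    assert h_uni < h_all
    assert h_all > 500.0                      # mosaic of many angles
    empty = elastic_reg.heterogeneity(np.zeros((8, 8), np.uint8),
                                      np.full((8, 8), np.nan), (0, 8, 0, 8))
    assert empty == 0.0


def test_expand_area_reaches_heterogeneity():
    slide = _mosaic_slide(12)
    params = ElasticParams()
    bbox = elastic_reg._content_bbox(slide)
    ty = (bbox[0] + bbox[1]) // 2 // params.tile_px
    tx = (bbox[2] + bbox[3]) // 2 // params.tile_px
    rect = elastic_reg.expand_area(slide, (ty, tx), params, bbox)
    y0, y1, x0, x1 = rect
    assert y1 > y0 and x1 > x0
    h = elastic_reg.heterogeneity(slide.category, slide.theta, rect)
    covers = (y0 <= bbox[0] and y1 >= bbox[1]
              and x0 <= bbox[2] and x1 >= bbox[3])
    assert h >= params.het_threshold_deg2 or covers


def test_match_energy_zero_for_identical():
    slide = _mosaic_slide(13)
    params = ElasticParams()
    rect = elastic_reg._content_bbox(slide)
    ident = TileTransform(centre=np.zeros(2))
    e = elastic_reg.match_energy(slide, slide, rect, ident, params)
    assert e == pytest.approx(0.0, abs=1e-9)


def test_match_energy_rises_with_rotation():
    slide = _mosaic_slide(14)
    params = ElasticParams()
    rect = elastic_reg._content_bbox(slide)
    c = np.array([(rect[2] + rect[3]) / 2.0, (rect[0] + rect[1]) / 2.0])
    e0 = elastic_reg.match_energy(slide, slide, rect,
                                  TileTransform(centre=c), params)
    e90 = elastic_reg.match_energy(
        slide, slide, rect, TileTransform(theta=90.0, centre=c), params)
    assert e90 > e0 + 0.2


def test_register_identical_slides_is_identity():
    slide = _mosaic_slide(15)
    warped, info = elastic_reg.register_slide(slide, slide)
    # every occupied tile keeps energy <= e_min, so no transform is applied
    for tt in info["tiles"].ravel():
        assert tt.is_identity
    pd.testing.assert_frame_equal(warped.nuclei, slide.nuclei)


def test_apply_warp_identity_grid_exact():
    slide = _mosaic_slide(16)
    tp = ElasticParams().tile_px
    h, w = slide.frame_shape
    grid = np.empty((h // tp, w // tp), dtype=object)
    for ty in range(grid.shape[0]):
        for tx in range(grid.shape[1]):
            grid[ty, tx] = TileTransform(centre=np.array(
                [tx * tp + tp / 2.0, ty * tp + tp / 2.0]))
    out = elastic_reg.apply_warp(slide.nuclei, grid, tp)
    np.testing.assert_allclose(out.x, slide.nuclei.x, atol=1e-9)
    np.testing.assert_allclose(out.y, slide.nuclei.y, atol=1e-9)
    np.testing.assert_allclose(out.theta_deg, slide.nuclei.theta_deg,
                               atol=1e-9)


def test_apply_warp_uniform_translation():
    slide = _mosaic_slide(17)
    tp = ElasticParams().tile_px
    h, w = slide.frame_shape
    grid = np.empty((h // tp, w // tp), dtype=object)
    for ty in range(grid.shape[0]):
        for tx in range(grid.shape[1]):
            grid[ty, tx] = TileTransform(
                t=np.array([3.0, -2.0]),
                centre=np.array([tx * tp + tp / 2.0, ty * tp + tp / 2.0]))
    out = elastic_reg.apply_warp(slide.nuclei, grid, tp)
    np.testing.assert_allclose(out.x, slide.nuclei.x + 3.0, atol=1e-9)
    np.testing.assert_allclose(out.y, slide.nuclei.y - 2.0, atol=1e-9)


def test_match_score_bounds():
    a = _mosaic_slide(18)
    assert elastic_reg.match_score(a, a) == pytest.approx(0.0, abs=1e-12)
    (b,), _ = fixtures.distort_stack([a], [(0.0, (40.0, 0.0))], 0.0, seed=1)
    s = elastic_reg.match_score(a, b)
    assert 0.0 < s <= 1.0


def test_order_and_register_identical_stack():
    base = _mosaic_slide(19)
    stack = []
    from myofield.regions import rebuild
    for k in range(4):
        s = rebuild(base)
        s.slide_number = k
        stack.append(s)
    res = elastic_reg.order_and_register(stack)
    assert not any(res["discard"])
    assert res["global_reference"] in range(4)
    assert max(res["scores"]) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        elastic_reg.order_and_register(stack[:2])
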