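import numpy as np
import pytest

from myofield import fixtures
from myofield.regions import CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL
from tests.conftest import counts_slide, headless_err_deg


def test_render_is_deterministic():
    spec = fixtures.PhantomSpec(theta=np.full((2, 2), 40.0), seed=9)
    img1, t1 = fixtures.render_slide(spec, 128)
    img2, t2 = fixtures.render_slide(
        fixtures.PhantomSpec(theta=np.full((2, 2), 40.0), seed=9), 128)
    assert np.array_equal(img1, img2)
    assert t1.equals(t2)


def test_render_validation():
    spec = fixtures.PhantomSpec(theta=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        fixtures.render_slide(spec, tile_px=32)
    dense = fixtures.PhantomSpec(theta=np.zeros((2, 2)), nuclear_density=1e5)
    with pytest.raises(ValueError, match="infeasible density"):
        fixtures.render_slide(dense, tile_px=64)
    with pytest.raises(ValueError):
        fixtures.PhantomSpec(theta=np.zeros((2, 2)), nuclear_density=-1.0)


def test_synth_regional_slide_recovers_field():
    theta = np.full((6, 6), 130.0)
    spec = fixtures.PhantomSpec(theta=theta, nuclear_density=10.0,
                                angle_noise_sd=4.0, seed=4)
    slide = fixtures.synth_regional_slide(spec)
    content = slide.category[slide.category != CAT_EMPTY]
    assert (content == CAT_PLANAR).mean() > 0.9
    th = slide.theta[~np.isnan(slide.theta)]
    d = np.abs(((th - 130.0) + 90.0) % 180.0 - 90.0)
    assert np.median(d) < 5.0


def test_synth_out_of_plane_regions_look_vertical():
    theta = np.zeros((4, 4))
    phi = np.full((4, 4), 80.0)          # steeply out of plane
    spec = fixtures.PhantomSpec(theta=theta, phi=phi, nuclear_density=10.0,
                                seed=2)
    slide = fixtures.synth_regional_slide(spec)
    content = slide.category[slide.category != CAT_EMPTY]
    assert (content == CAT_VERTICAL).mean() > 0.8


def test_blob_mask_contiguous_with_holes():
    mask = fixtures.blob_mask((200, 100), seed=3, n_holes=2)
    assert 0.2 < mask.mean() < 0.8
    from scipy import ndimage
    _, n = ndimage.label(mask)
    assert n == 1                         # one connected cross-section
    _, nh = ndimage.label(~mask)
    assert nh >= 3                        # outside + at least 2 holes


def test_patch_field_gaps_on_boundaries():
    theta, mask = fixtures.patch_field((40, 40), 8, seed=1)
    assert theta.shape == mask.shape == (40, 40)
    assert (theta >= 0).all() and (theta < 180).all()
    assert 0 < (~mask).sum() < mask.size / 2
    no_gap_theta, no_gap = fixtures.patch_field((40, 40), 8, seed=1, gap=False)
    assert no_gap.all()
    np.testing.assert_allclose(theta, no_gap_theta)


def test_elastic_warp_amplitude_and_smoothness():
    rng = np.random.default_rng(5)
    w = fixtures.ElasticWarp(6.0, ((0.0, 100.0), (0.0, 50.0)), rng)
    g = np.stack(np.meshgrid(np.linspace(0, 50, 30),
                             np.linspace(0, 100, 60)), axis=-1).reshape(-1, 2)
    d = w(g)
    # normalization targets the maximum on a coarse probe grid; allow the
    # small refinement excess of the finer evaluation grid
    assert np.linalg.norm(d, axis=1).max() <= 6.0 * 1.02
    # displacements vary smoothly: neighbouring samples differ slightly
    dd = np.linalg.norm(np.diff(d.reshape(60, 30, 2), axis=1), axis=-1)
    assert dd.max() < 1.5


def test_distort_stack_ground_truth_closure():
    mask = fixtures.blob_mask((60, 30), seed=2)
    s0 = counts_slide(mask, 6.0, 3, frame=(200, 100))
    (s1,), (gt,) = fixtures.distort_stack([s0], [(7.0, (3.0, -4.0))],
                                          elastic_amplitude=2.0, seed=8)
    x, y = fixtures._rigid_apply(s0.nuclei.x.to_numpy(),
                                 s0.nuclei.y.to_numpy(),
                                 gt["theta"], gt["t"], gt["centre"])
    d = gt["warp"](np.column_stack([x, y]))
    np.testing.assert_allclose(s1.nuclei.x, x + d[:, 0], atol=1e-9)
    np.testing.assert_allclose(s1.nuclei.y, y + d[:, 1], atol=1e-9)
    np.testing.assert_allclose(
        s1.nuclei.theta_deg, (s0.nuclei.theta_deg + 7.0) % 180.0, atol=1e-9)


def test_distort_stack_amplitude_guard():
    mask = fixtures.blob_mask((60, 30), seed=2)
    s0 = counts_slide(mask, 6.0, 3, frame=(64, 32))   # ~1-region margin
    with pytest.raises(ValueError, match="amplitude"):
        fixtures.distort_stack([s0], None, elastic_amplitude=50.0)


def test_phantom_volume_geometries():
    ph = fixtures.phantom_volume("slab", (16, 24, 24), bundle_width_vox=8)
    assert ph.category.shape == (16, 24, 24)
    assert set(np.unique(ph.labels)) == {0, 1}
    assert ph.widths_um[1] == pytest.approx(8 * ph.pitch_um)
    norms = np.linalg.norm(ph.vec[ph.labels == 1], axis=-1)
    np.testing.assert_allclose(norms, 1.0)

    cyl = fixtures.phantom_volume("cylinder", (16, 24, 24), bundle_width_vox=10)
    assert (cyl.category[cyl.labels == 1] == CAT_VERTICAL).all()
    assert np.isnan(cyl.theta[cyl.labels == 1]).all()

    tl = fixtures.phantom_volume("two_layer", (16, 16, 16))
    assert set(np.unique(tl.labels)) == {1, 2}   # the layers fill the volume
    assert headless_err_deg(tl.vec[0, 0, 0], np.array([1.0, 0, 0])) < 1e-9
    assert headless_err_deg(tl.vec[-1, 0, 0], np.array([0, 1.0, 0])) < 1e-9

    inc = fixtures.phantom_volume("inclined_slab", (20, 16, 20),
                                  elevation_deg=30.0, bundle_width_vox=4)
    v = inc.vec[inc.labels == 1][0]
    assert np.degrees(np.arcsin(abs(v[2]))) == pytest.approx(30.0, abs=1e-6)


def test_phantom_volume_validation():
    with pytest.raises(ValueError):
        fixtures.phantom_volume("slab", (8, 24, 24))
    with pytest.raises(ValueError, match="unresolvable"):
        fixtures.phantom_volume("slab", (16, 24, 24), bundle_width_vox=1.0)
    with pytest.raises(ValueError, match="unknown geometry"):
        fixtures.phantom_volume("torus", (16, 24, 24))


def test_stereology_sample_monotone_in_elevation():
    flat = fixtures.stereology_sample(400, 0.0, n_planes=1500, seed=1)
    steep = fixtures.stereology_sample(400, 90.0, n_planes=1500, seed=1)
    # steeper fibres cross the section plane more often
    assert steep > 2.0 * flat
    assert flat > 0.0
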