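import numpy as np
import pandas as pd
import pytest

from myofield import fixtures, metrics
from myofield.config import WidthParams


def test_final_smooth_uniform_field_fixed_point():
    shape = (6, 8, 8)
    vec = np.zeros(shape + (3,))
    vec[..., 0] = 1.0
    weight = np.ones(shape)
    exclude = np.zeros(shape, dtype=bool)
    out_v, out_w = metrics.final_smooth(vec, weight, exclude)
    # a uniform unit field with uniform weight is invariant (the stencil is
    # mass-renormalized, so boundaries do not fade)
    np.testing.assert_allclose(np.abs(out_v[..., 0]), 1.0, atol=1e-12)
    np.testing.assert_allclose(out_w, 1.0, atol=1e-12)


def test_final_smooth_sign_alignment():
    # equal headless vectors stored with opposite signs must reinforce,
    # not cancel
    shape = (1, 1, 4)
    vec = np.zeros(shape + (3,))
    vec[..., 0] = [[[1.0, -1.0, 1.0, -1.0]]]
    weight = np.ones(shape)
    out_v, out_w = metrics.final_smooth(vec, weight,
                                        np.zeros(shape, dtype=bool))
    np.testing.assert_allclose(np.abs(out_v[..., 0]), 1.0, atol=1e-12)
    np.testing.assert_allclose(out_w, 1.0, atol=1e-12)


def test_final_smooth_respects_exclusion():
    shape = (3, 5, 5)
    vec = np.zeros(shape + (3,))
    vec[..., 0] = 1.0
    vec[1, 2, 2] = (0.0, 1.0, 0.0)        # deviant excluded voxel
    weight = np.ones(shape)
    exclude = np.zeros(shape, dtype=bool)
    exclude[1, 2, 2] = True
    out_v, out_w = metrics.final_smooth(vec, weight, exclude)
    assert out_w[1, 2, 2] == 0.0
    assert not out_v[1, 2, 2].any()
    # neighbours never see the excluded voxel
    np.testing.assert_allclose(np.abs(out_v[1, 2, 1, 0]), 1.0, atol=1e-12)


def test_smooth_slide_2d_uniform_and_edge():
    cat = np.ones((10, 10), dtype=np.uint8)
    th = np.full((10, 10), 25.0)
    exclude = np.zeros((10, 10), dtype=bool)
    exclude[4, 4] = True
    pl, sm = metrics.smooth_slide_2d(cat, th, exclude)
    assert not pl[4, 4] and np.isnan(sm[4, 4])
    ok = pl & ~np.isnan(sm)
    np.testing.assert_allclose(sm[ok], 25.0, atol=1e-9)


def test_measure_widths_2d_slab():
    ph = fixtures.phantom_volume("slab", (16, 32, 32), bundle_width_vox=10)
    planar = ph.category[0] == 1
    theta = np.nan_to_num(ph.theta[0])
    w = metrics.measure_widths_2d(planar, theta, ph.pitch_um,
                                  rng=np.random.default_rng(5))
    assert len(w) > 5
    errs = np.abs(w.width_um / ph.pitch_um - 10.0)
    assert errs.max() <= 1.0


def test_measure_widths_no_samples_raises():
    with pytest.raises(ValueError, match="no samples"):
        metrics.measure_widths_2d(np.zeros((8, 8), bool), np.zeros((8, 8)),
                                  47.5)
    with pytest.raises(ValueError, match="no samples"):
        metrics.measure_widths_3d(np.zeros((8, 8, 8, 3)),
                                  np.zeros((8, 8, 8)), 47.5)


def test_measure_widths_3d_cylinder_perpendicular():
    ph = fixtures.phantom_volume("cylinder", (16, 24, 24),
                                 bundle_width_vox=10)
    params = WidthParams(grid_regions=2, grid_z=2)
    w = metrics.measure_widths_3d(ph.vec, ph.weight, ph.pitch_um, params,
                                  np.random.default_rng(3))
    assert len(w) > 20
    # perpendicular sampling directions are orthogonal to the axis (z)
    np.testing.assert_allclose(w.uz, 0.0, atol=1e-9)
    widths_vox = w.width_um / ph.pitch_um
    # chords of a diameter-10 disc: each arm overshoots by at most one step
    # plus the half-voxel containing-voxel test
    assert widths_vox.max() <= 12.0 + 1e-9
    assert 5.0 <= widths_vox.median() <= 11.0


def test_equivalence_same_sample_equivalent():
    rng = np.random.default_rng(0)
    w = np.exp(rng.normal(5.0, 0.4, 4000))
    rep = metrics.equivalence_stats(w, w, rng=np.random.default_rng(1))
    assert rep.mean_log_diff == pytest.approx(0.0, abs=1e-12)
    assert rep.mean_equivalent and rep.ks_equivalent
    assert rep.verdict == "equivalent"
    assert rep.ks_prob > 0.95
    assert rep.n_u == rep.n_r == 4000


def test_equivalence_shift_detected():
    rng = np.random.default_rng(2)
    a = np.exp(rng.normal(5.0, 0.4, 4000))
    rep = metrics.equivalence_stats(a, 1.2 * a, rng=np.random.default_rng(3))
    assert rep.verdict == "not_equivalent"
    assert not rep.mean_equivalent
    assert rep.mean_log_diff == pytest.approx(-np.log(1.2), abs=1e-9)


def test_equivalence_requires_sample_size():
    with pytest.raises(ValueError):
        metrics.equivalence_stats(np.ones(100), np.ones(2000))


def test_width_maps_medians():
    samples = pd.DataFrame({
        "x": [1, 1, 2, 2], "y": [3, 3, 3, 3], "z": [0, 0, 1, 1],
        "ux": 0.0, "uy": 0.0, "uz": 0.0,
        "width_um": [10.0, 20.0, 30.0, 50.0]})
    maps = metrics.width_maps(samples, (2, 5, 5))
    assert maps["column_median"][3, 1] == 15.0
    assert maps["column_median"][3, 2] == 40.0
    per_z = maps["per_z"].set_index("z")
    assert per_z.loc[0, "median_um"] == 15.0
    assert per_z.loc[1, "n"] == 2
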