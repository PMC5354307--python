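import numpy as np
import pandas as pd
import pytest

from myofield import regions
from myofield.config import RegionParams, ResolutionConfig
from myofield.regions import CAT_EMPTY, CAT_PLANAR, CAT_VERTICAL

CFG = ResolutionConfig()


def test_classify_empty_below_min_count():
    px = regions.classify_region([], [], count_all=3.0)
    assert px.category == CAT_EMPTY
    assert px.count == 0.0
    px = regions.classify_region([2.5], [30.0])
    assert px.category == CAT_EMPTY
    assert px.count == 1.0


def test_classify_planar_aligned():
    aspects = [2.5, 3.0, 2.2, 2.8]
    thetas = [40.0, 42.0, 44.0, 41.0]
    px = regions.classify_region(aspects, thetas)
    assert px.category == CAT_PLANAR
    assert abs(px.theta - 42.0) < 3.0
    assert px.count == 4.0


def test_classify_vertical_by_roundness():
    # aspect below 1.6: vertical class only; fraction 1 > 5/9
    px = regions.classify_region([1.2, 1.1, 1.4], [0.0, 60.0, 120.0])
    assert px.category == CAT_VERTICAL
    assert px.theta is None


def test_classify_band_counts_both():
    # aspects in [1.6, 2.0] count for both classes; fraction 3/6 = 1/2 < 5/9
    # keeps the region planar when angles agree
    px = regions.classify_region([1.8, 1.7, 1.9], [10.0, 12.0, 11.0])
    assert px.category == CAT_PLANAR


def test_classify_vertical_by_iqr():
    rng = np.random.default_rng(0)
    thetas = rng.uniform(0, 180, 40)
    aspects = np.full(40, 2.5)
    px = regions.classify_region(aspects, thetas)
    assert px.category == CAT_VERTICAL


def test_classify_fraction_threshold():
    # 5 round vs 4 elongated: 5/9 is NOT > 5/9, stays planar
    aspects = [1.2] * 5 + [2.5] * 4
    thetas = [20.0] * 9
    assert regions.classify_region(aspects, thetas).category == CAT_PLANAR
    # 6 round vs 4 elongated: 6/10 > 5/9, vertical
    aspects = [1.2] * 6 + [2.5] * 4
    assert regions.classify_region(aspects, [20.0] * 10).category == CAT_VERTICAL


def test_classify_divisor_averages_counts():
    px = regions.classify_region([2.5] * 6, [10.0] * 6, count_all=8.0,
                                 count_small=2.0, divisor=2.0)
    assert px.count == 3.0
    assert px.count_all == 4.0
    assert px.count_small == 1.0


def _table(xs, ys, theta=20.0, aspect=2.5, area=30.0):
    n = len(xs)
    return pd.DataFrame({"cx": xs, "cy": ys,
                         "theta_deg": np.full(n, theta),
                         "aspect": np.full(n, aspect),
                         "area_um2": np.full(n, area)})


def test_nuclei_to_region_coords_centres_content():
    t = _table([64.0, 200.0], [64.0, 300.0])
    out = regions.nuclei_to_region_coords(t, CFG, content_px=(512, 384))
    rows, cols = 4, 3
    top, left = (1600 - rows) // 2, (800 - cols) // 2
    assert out.x.iloc[0] == pytest.approx(left + 0.5)
    assert out.y.iloc[0] == pytest.approx(top + 0.5)
    assert out.sm.all()
    assert not out.small.any()


def test_nuclei_to_region_coords_overflow():
    t = _table([0.0], [0.0])
    with pytest.raises(ValueError, match="frame overflow"):
        regions.nuclei_to_region_coords(t, CFG, content_px=(1601 * 128, 128))


def test_grid_from_nuclei_counts_and_classification():
    rng = np.random.default_rng(1)
    n = 30
    nuc = pd.DataFrame({
        "x": 10 + rng.uniform(0, 1, n), "y": 20 + rng.uniform(0, 1, n),
        "theta_deg": rng.normal(90.0, 4.0, n) % 180.0,
        "aspect": np.full(n, 2.5), "area_um2": np.full(n, 30.0),
        "sm": np.ones(n, dtype=bool), "small": np.zeros(n, dtype=bool)})
    planes = regions.grid_from_nuclei(nuc, (40, 40))
    assert planes["category"][20, 10] == CAT_PLANAR
    assert planes["count"][20, 10] == n
    assert abs(planes["theta"][20, 10] - 90.0) < 5.0
    assert planes["category"].sum() == CAT_PLANAR  # single occupied region


def test_grid_counts_only_fast_path_matches_counts():
    rng = np.random.default_rng(2)
    n = 200
    nuc = pd.DataFrame({
        "x": rng.uniform(0, 8, n), "y": rng.uniform(0, 8, n),
        "theta_deg": rng.uniform(0, 180, n),
        "aspect": np.full(n, 2.5), "area_um2": np.full(n, 30.0),
        "sm": np.ones(n, dtype=bool), "small": np.zeros(n, dtype=bool)})
    full = regions.grid_from_nuclei(nuc, (8, 8))
    fast = regions.grid_from_nuclei(nuc, (8, 8), classify=False)
    np.testing.assert_allclose(full["count"], fast["count"])
    np.testing.assert_allclose(full["count_all"], fast["count_all"])
    # fast path marks every sufficiently occupied region planar
    assert ((fast["category"] != CAT_EMPTY)
            == (fast["count"] >= RegionParams().min_count)).all()


def test_grid_drops_out_of_frame_nuclei():
    nuc = pd.DataFrame({
        "x": [-1.0, 3.0, 3.2, 99.0], "y": [2.0, 3.0, 3.4, 2.0],
        "theta_deg": [10.0] * 4, "aspect": [2.5] * 4,
        "area_um2": [30.0] * 4, "sm": [True] * 4, "small": [False] * 4})
    planes = regions.grid_from_nuclei(nuc, (8, 8))
    assert planes["count_all"].sum() == 2


def test_pad_and_grid_round_trip():
    t = _table([64.0, 70.0, 60.0], [64.0, 60.0, 70.0])
    slide = regions.pad_and_grid(t, CFG, slide_number=7)
    assert slide.frame_shape == (1600, 800)
    assert slide.slide_number == 7
    assert slide.pitch_um == pytest.approx(CFG.pitch_um)
    assert slide.nonempty_count() == 1


def test_rebuild_preserves_metadata_and_counts_only_flag():
    t = _table([64.0, 70.0, 60.0], [64.0, 60.0, 70.0])
    slide = regions.pad_and_grid(t, CFG, slide_number=3)
    moved = slide.nuclei.copy()
    moved["x"] += 5.0
    out = regions.rebuild(slide, moved)
    assert out.slide_number == 3
    assert out.count.sum() == slide.count.sum()
    assert np.argmax(out.count.sum(axis=0)) == np.argmax(slide.count.sum(axis=0)) + 5
    slide.flags["counts_only"] = True
    out2 = regions.rebuild(slide, moved)
    np.testing.assert_allclose(out2.count, out.count)
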