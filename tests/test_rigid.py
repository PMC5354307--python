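import numpy as np
import pytest

from myofield import fixtures, rigid_reg
from myofield.config import RigidParams
from myofield.rigid_reg import RigidTransform
from tests.conftest import counts_slide


def test_transform_algebra():
    r = RigidTransform.rotation(30.0, (5.0, 7.0))
    t = RigidTransform.translation((2.0, -3.0))
    comp = t.compose(r)
    p = np.array([[1.0, 2.0], [5.0, 7.0]])
    np.testing.assert_allclose(comp(p), t(r(p)), atol=1e-12)
    assert comp.theta_deg == pytest.approx(30.0)
    # rotation about its own centre fixes the centre
    np.testing.assert_allclose(r(np.array([[5.0, 7.0]])), [[5.0, 7.0]])
    assert RigidTransform.identity().is_identity()
    assert not comp.is_identity()


def test_edge_image_outlines_content():
    mask = fixtures.blob_mask((120, 60), seed=1)
    slide = counts_slide(mask, 8.0, 2, frame=(200, 100))
    edges = rigid_reg.edge_image(slide)
    assert edges.ndim == 2 and edges.shape[1] == 2
    assert len(edges) > 50
    # edges hug the content: all within the frame, none deep inside padding
    assert (edges[:, 0] >= 0).all() and (edges[:, 0] < 100).all()
    assert (edges[:, 1] >= 0).all() and (edges[:, 1] < 200).all()


def test_edge_image_empty_slide():
    slide = counts_slide(np.zeros((40, 20), dtype=bool), 5.0, 1,
                         frame=(100, 50))
    assert len(rigid_reg.edge_image(slide)) == 0


def _ring_edges(n=300, r=30.0, centre=(50.0, 50.0), seed=0):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 2 * np.pi, n)
    rr = r + rng.uniform(-6, 6, n)       # rough annulus: rotation-sensitive
    pts = np.column_stack([centre[0] + rr * np.cos(a),
                           centre[1] + rr * np.sin(a)])
    return np.rint(pts)


def test_hough_translate_recovers_shift():
    e0 = _ring_edges()
    for d in ((13, -8), (0, 0), (-21, 30)):
        e1 = e0 + d
        t = rigid_reg.hough_translate(e1, e0, 64, (128, 128))
        # the 1-px coincidence tolerance makes every shift within one pixel
        # of the exact inverse score identically; ties go to the smaller |t|
        assert max(abs(t[0] + d[0]), abs(t[1] + d[1])) <= 1


def test_hough_rotate_recovers_rotation():
    e0 = _ring_edges(seed=3)
    c = np.array([50.0, 50.0])
    for ang in (4.0, -7.0):
        rot = RigidTransform.rotation(ang, c)
        e1 = rot(e0)
        th, centre = rigid_reg.hough_rotate(e1, e0, np.array([c]), 10.0, c)
        assert th == pytest.approx(-ang, abs=1.0)
        np.testing.assert_allclose(centre, c)


def test_coincidence_tolerance_one_pixel():
    e0 = np.array([[10.0, 10.0]])
    frame = (32, 32)
    assert rigid_reg.coincidence(np.array([[11.0, 10.0]]), e0, frame) == 1
    assert rigid_reg.coincidence(np.array([[11.0, 11.0]]), e0, frame) == 1
    assert rigid_reg.coincidence(np.array([[12.0, 10.0]]), e0, frame) == 0


def test_register_pair_small_transform():
    mask = fixtures.blob_mask((160, 80), seed=4, n_holes=2)
    s0 = counts_slide(mask, 6.0, 5, frame=(256, 128))
    (s1,), (gt,) = fixtures.distort_stack([s0], [(3.0, (6.0, -9.0))], 0.0,
                                          seed=6)
    e1 = rigid_reg.edge_image(s1)
    e0 = rigid_reg.edge_image(s0)
    params = RigidParams(n_steps=4, frame_w=128,
                         rotation_bounds=(10.0, 5.0, 2.5, 1.25))
    T = rigid_reg.register_pair(e1, e0, s0.frame_shape, params)
    c = np.array(gt["centre"])
    fwd = fixtures._rigid_apply(c[0], c[1], gt["theta"], gt["t"], c)
    rec = T(np.array([fwd]))[0]
    # the shortened 4-step protocol trades angular resolution for speed, so
    # only coarse recovery is asserted here; full-protocol accuracy is
    # covered by the acceptance suite
    assert abs(T.theta_deg + gt["theta"]) <= 2.5
    assert np.hypot(*(rec - c)) <= 4.0
    # the recovered transform overlays most edges within the 1-px tolerance
    frac = rigid_reg.coincidence(T(e1), e0, s0.frame_shape) / len(e1)
    assert frac >= 0.8


def test_register_pair_requires_edges():
    with pytest.raises(ValueError):
        rigid_reg.register_pair(np.zeros((0, 2)), _ring_edges(), (128, 128))


def test_stack_registration_flags_empty_slides():
    mask = fixtures.blob_mask((120, 60), seed=7)
    s0 = counts_slide(mask, 6.0, 8, frame=(200, 100), num=0)
    empty = counts_slide(np.zeros((40, 20), bool), 5.0, 1,
                         frame=(200, 100), num=1)
    params = RigidParams(n_steps=3, frame_w=64,
                         rotation_bounds=(5.0, 2.5, 1.25))
    out, transforms = rigid_reg.rigid_register_stack([s0, empty], params)
    assert out[1].flags.get("rigid_unregistered")
    assert transforms[1].is_identity()
    assert transforms[0].is_identity()
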