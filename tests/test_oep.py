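"""Equation-level tests of the object evaluation parameter."""

from __future__ import annotations

import numpy as np
import pytest

from autofoci import detection, oep
from autofoci.oep import ChannelFeatures
from tests.conftest import make_cell


def test_compactness_hand_example():
    # two pixels one apart, equal intensity 1: centroid at the midpoint,
    # each at r^2 = 0.25, so sum r_i^2 I_i = 0.5 and C = 2
    img = np.zeros((5, 5))
    img[2, 2] = img[2, 3] = 1.0
    pix = np.array([[2, 2], [2, 3]])
    assert oep.compactness(pix, img) == pytest.approx(2.0)


def test_compactness_weighted_centroid():
    # intensities 3 and 1 one apart: centroid at 0.25 from the brighter
    # pixel; sum r^2 I = 0.0625*3 + 0.5625*1 = 0.75 -> C = 4/3
    img = np.zeros((5, 5))
    img[2, 2], img[2, 3] = 3.0, 1.0
    pix = np.array([[2, 2], [2, 3]])
    assert oep.compactness(pix, img) == pytest.approx(4.0 / 3.0)


def test_compactness_degenerate_is_infinite():
    img = np.zeros((3, 3))
    img[1, 1] = 5.0
    assert np.isinf(oep.compactness(np.array([[1, 1]]), img))


def test_channel_oep_substitution():
    # (I_TH / I_nucl) * I_LC * C = (20/10) * 3 * 5 = 30
    f = ChannelFeatures(i_th=20.0, i_lc=3.0, i_nucl=10.0, c=5.0)
    assert oep.channel_oep(f) == pytest.approx(30.0)


def test_channel_oep_clamps_negative_curvature():
    f = ChannelFeatures(i_th=20.0, i_lc=-3.0, i_nucl=10.0, c=5.0)
    assert oep.channel_oep(f) == 0.0


def test_combined_oep_weighting():
    # OEP_red^w * OEP_green^(1/w) with w = 2: 4^2 * 16^0.5 = 64
    assert oep.combined_oep(4.0, 16.0, 2.0) == pytest.approx(64.0)


def test_combined_oep_w1_is_plain_product():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b = rng.uniform(0, 100, size=2)
        assert oep.combined_oep(a, b, 1.0) == pytest.approx(a * b)


def test_combined_oep_validation():
    with pytest.raises(ValueError):
        oep.combined_oep(1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        oep.combined_oep(-1.0, 1.0, 1.0)


def test_weight_factor_and_degenerate_channels():
    img = np.zeros((20, 20))
    img[10, 10] = 50.0
    cell = make_cell(img)
    cell.i_std_red, cell.i_std_green = 2.4, 2.0
    assert oep.weight_factor(cell) == pytest.approx(1.2)
    cell.i_std_green = 0.0
    with pytest.raises(oep.DegenerateChannelError):
        oep.weight_factor(cell)


def _gauss_cell(seed=0, amp_scale=1.0):
    """A cell with two blobs on a noisy baseline (float path, no clipping)."""
    rng = np.random.default_rng(seed)
    img = rng.uniform(9, 11, size=(60, 60)) * amp_scale
    rr, cc = np.mgrid[0:60, 0:60]
    for (r, c, a) in [(20, 20, 150.0), (40, 42, 90.0)]:
        img += a * amp_scale * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.5**2))
    return img


def test_oep_scale_invariance():
    """Multiplying every intensity by k leaves the combined OEP unchanged:
    I_TH/I_nucl is a ratio, I_LC scales with k but C scales with 1/k, and
    the weight w is a ratio of standard deviations (unquantized path)."""
    base = _gauss_cell(seed=1, amp_scale=1.0)
    for k in (0.5, 3.0, 17.0):
        scaled = _gauss_cell(seed=1, amp_scale=k)
        assert np.allclose(scaled, base * k)
        recs = {}
        for tag, img in (("base", base), ("scaled", scaled)):
            cell = make_cell(img, green=img.copy())
            objs = detection.detect_objects(cell)
            assert len(objs) == 2
            recs[tag] = oep.score_objects(cell, objs)
        for rb, rs in zip(recs["base"], recs["scaled"]):
            assert rs.oep == pytest.approx(rb.oep, rel=1e-9)
            assert rs.w == pytest.approx(rb.w, rel=1e-9)


def test_oep_monotone_in_top_hat_intensity():
    """With everything else fixed, a higher I_TH gives a higher score."""
    f1 = ChannelFeatures(i_th=10.0, i_lc=3.0, i_nucl=10.0, c=5.0)
    f2 = ChannelFeatures(i_th=11.0, i_lc=3.0, i_nucl=10.0, c=5.0)
    assert oep.channel_oep(f2) > oep.channel_oep(f1)


def test_weight_shifts_combined_score_toward_crisper_channel():
    # red > 1 > green: increasing w (crisper red) must increase the score
    lo = oep.combined_oep(10.0, 0.1, 0.5)
    hi = oep.combined_oep(10.0, 0.1, 2.0)
    assert hi > lo


def test_score_objects_caps_degenerate_compactness():
    img = np.full((30, 30), 10.0)
    rr, cc = np.mgrid[0:30, 0:30]
    img += 150 * np.exp(-((rr - 10) ** 2 + (cc - 10) ** 2) / (2 * 1.5**2))
    img[24, 24] = 200.0  # isolated bright pixel -> degenerate object
    cell = make_cell(img)
    objs = detection.detect_objects(cell, min_area=1)
    assert any(o.area == 1 for o in objs)
    recs = oep.score_objects(cell, objs)
    assert all(np.isfinite(r.oep) for r in recs)
    finite_c = [o.features["c_red"] for o in objs if o.area >= 2]
    degen_c = [o.features["c_red"] for o in objs if o.area == 1]
    assert degen_c and finite_c
    assert max(degen_c) <= max(finite_c)  # capped at the per-cell maximum


def test_attach_log_scores():
    from autofoci.core import OEPRecord

    recs = [
        OEPRecord("c", i, 1.0, 1.0, 1.0, v)
        for i, v in enumerate([100.0, 1e-3, 0.0])
    ]
    oep.attach_log_scores(recs)
    assert recs[0].log_oep == pytest.approx(2.0)
    assert recs[0].inv_log_oep == pytest.approx(0.5)
    assert recs[1].log_oep == pytest.approx(-3.0)
    assert recs[1].inv_log_oep is None  # only defined for OEP > 1
    assert recs[2].log_oep == pytest.approx(-3.0)  # floored at min positive
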