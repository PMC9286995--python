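"""Dice, contour extraction, APD, good-contour rule, case bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_disc
from lvseg import metrics as met
from lvseg.metrics import (
    Contour,
    apd,
    classify_good,
    dice,
    evaluate_case,
    mask_to_contour,
    summarize,
)


class TestDice:
    def test_identity_is_one(self):
        m = make_disc(32, (16, 16), 6)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[2:4, 2:4] = True
        b[10:12, 10:12] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True  # 100 px
        b[5:15, 0:10] = True  # 100 px, 50 shared
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_an_error(self):
        z = np.zeros((8, 8), bool)
        with pytest.raises(ValueError, match="undefined"):
            dice(z, z)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_random_pairs_match_pixel_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        if not (a.any() or b.any()):
            return
        inter = np.logical_and(a, b).sum()
        expected = 2.0 * inter / (a.sum() + b.sum())
        got = dice(a, b)
        assert got == pytest.approx(expected)
        assert got == dice(b, a)
        assert 0.0 <= got <= 1.0


class TestMaskToContour:
    def test_square_perimeter(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True  # 10x10 square
        c = mask_to_contour(m)
        seg = np.diff(np.vstack([c.points, c.points[:1]]), axis=0)
        perimeter = np.hypot(seg[:, 0], seg[:, 1]).sum()
        assert perimeter == pytest.approx(40.0, rel=0.05)

    def test_disc_area_shoelace(self):
        m = make_disc(64, (32, 32), 20)
        c = mask_to_contour(m)
        x, y = c.points[:, 0], c.points[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert area == pytest.approx(np.pi * 400, rel=0.02)

    def test_rasterization_roundtrip(self):
        from skimage.draw import polygon

        m = make_disc(64, (30, 33), 15)
        c = mask_to_contour(m)
        rr, cc = polygon(c.points[:, 1], c.points[:, 0], shape=m.shape)
        recovered = np.zeros_like(m)
        recovered[rr, cc] = True
        assert dice(m, recovered) >= 0.98

    def test_empty_and_multicomponent_masks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_contour(np.zeros((8, 8), bool))
        two = np.zeros((16, 16), bool)
        two[2:4, 2:4] = True
        two[10:12, 10:12] = True
        with pytest.raises(ValueError, match="2 connected components"):
            mask_to_contour(two)


def _dense_apd_oracle(pa: np.ndarray, pb: np.ndarray) -> float:
    """Brute-force symmetric mean point-to-segment distance (mm units in)."""

    def point_to_polyline(p, poly):
        a = poly
        b = np.roll(poly, -1, axis=0)
        ab = b - a
        t = np.clip(((p - a) * ab).sum(1) / (ab * ab).sum(1).clip(1e-12), 0, 1)
        proj = a + t[:, None] * ab
        return np.sqrt(((p - proj) ** 2).sum(1)).min()

    d_ab = np.mean([point_to_polyline(p, pb) for p in pa])
    d_ba = np.mean([point_to_polyline(p, pa) for p in pb])
    return 0.5 * (d_ab + d_ba)


class TestApd:
    def test_self_distance_zero(self):
        c = mask_to_contour(make_disc(64, (32, 32), 12), spacing=1.0)
        assert apd(c, c) == pytest.approx(0.0, abs=1e-9)

    @staticmethod
    def _circle(radius, center=(32.0, 32.0), n=256):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        return Contour(pts, spacing=1.0)

    def test_concentric_circles_radius_gap(self):
        ca = self._circle(10.0)
        cb = self._circle(12.0)
        got = apd(ca, cb)
        oracle = _dense_apd_oracle(ca.points_mm(), cb.points_mm())
        assert got == pytest.approx(2.0, abs=0.1)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_concentric_rasterized_discs_radius_gap(self):
        """Mask-derived contours keep the gap within discretization error."""
        ca = mask_to_contour(make_disc(64, (32, 32), 10), spacing=1.0)
        cb = mask_to_contour(make_disc(64, (32, 32), 12), spacing=1.0)
        assert apd(ca, cb) == pytest.approx(2.0, abs=0.25)

    def test_spacing_scales_linearly(self):
        a = mask_to_contour(make_disc(64, (32, 32), 10))
        b = mask_to_contour(make_disc(64, (30, 34), 12))
        base = apd(Contour(a.points, 1.0), Contour(b.points, 1.0))
        scaled = apd(Contour(a.points, 1.5), Contour(b.points, 1.5))
        assert scaled == pytest.approx(1.5 * base, rel=1e-9)

    def test_symmetry_and_translation_invariance(self):
        a = mask_to_contour(make_disc(64, (30, 30), 10))
        b = mask_to_contour(make_disc(64, (33, 31), 12))
        assert apd(a, b) == pytest.approx(apd(b, a))
        shift = np.array([3.0, -2.0])
        a2 = Contour(a.points + shift, 1.0)
        b2 = Contour(b.points + shift, 1.0)
        assert apd(a2, b2) == pytest.approx(apd(a, b), abs=1e-9)

    def test_spacing_mismatch_rejected(self):
        a = mask_to_contour(make_disc(32, (16, 16), 6), spacing=1.0)
        b = mask_to_contour(make_disc(32, (16, 16), 8), spacing=2.0)
        with pytest.raises(ValueError, match="spacing"):
            apd(a, b)


class TestClassifyGood:
    def test_worked_slice_boundaries(self):
        # 4.85 mm is a good contour, 6.25 mm is poor, 5.0 is strictly out
        assert classify_good(4.85) is True
        assert classify_good(6.25) is False
        assert classify_good(5.0) is False


class TestEvaluateCase:
    @staticmethod
    def _case(n_good: int, n_bad: int, size=48):
        gt = make_disc(size, (24, 24), 10)
        good_pred = make_disc(size, (24, 24), 10.5)  # sub-mm APD
        bad_pred = make_disc(size, (24, 38), 8)      # far displaced
        preds = [good_pred] * n_good + [bad_pred] * n_bad
        gts = [gt] * (n_good + n_bad)
        return preds, gts

    def test_pgc_twelve_of_thirteen(self):
        cm = evaluate_case(*self._case(12, 1), spacing=1.0)
        assert cm.pgc_percent == pytest.approx(92.31, abs=0.005)
        assert cm.n_good == 12

    def test_pgc_seventeen_of_eighteen(self):
        cm = evaluate_case(*self._case(17, 1), spacing=1.0)
        assert cm.pgc_percent == pytest.approx(94.44, abs=0.005)

    def test_all_good_and_identical(self):
        gt = make_disc(48, (24, 24), 10)
        cm = evaluate_case([gt] * 4, [gt] * 4, spacing=1.0)
        assert cm.pgc_percent == 100.0
        assert cm.mean_dm_of_good == pytest.approx(1.0)
        assert cm.mean_apd_of_good == pytest.approx(0.0, abs=1e-9)

    def test_empty_prediction_counts_against_pgc_only(self):
        gt = make_disc(48, (24, 24), 10)
        empty = np.zeros_like(gt)
        cm = evaluate_case([gt, empty], [gt, gt], spacing=1.0)
        assert cm.pgc_percent == pytest.approx(50.0)
        # the empty slice is excluded from the DM/APD means
        assert cm.mean_dm_of_good == pytest.approx(1.0)

    def test_good_slices_all_below_threshold(self):
        cm = evaluate_case(*self._case(3, 2), spacing=1.0)
        for ev in cm.slice_evals:
            if ev.good:
                assert ev.apd_mm < met.GOOD_APD_MM

    def test_length_mismatch_rejected(self):
        gt = make_disc(48, (24, 24), 10)
        with pytest.raises(ValueError, match="predictions"):
            evaluate_case([gt], [gt, gt], spacing=1.0)


class TestSummarize:
    def test_single_case_mean_is_case_sd_zero(self):
        cm = evaluate_case([make_disc(48, (24, 24), 10)] * 2,
                           [make_disc(48, (24, 24), 10)] * 2, spacing=1.0)
        s = summarize([cm])
        assert s.pgc_mean == cm.pgc_percent and s.pgc_sd == 0.0

    def test_hand_listed_triple_matches_direct_formula(self):
        vals = [90.0, 95.0, 100.0]
        cases = []
        for v in vals:
            cm = evaluate_case([make_disc(48, (24, 24), 10)] * 2,
                               [make_disc(48, (24, 24), 10)] * 2, spacing=1.0)
            cm.pgc_percent = v
            cases.append(cm)
        s = summarize(cases)
        assert s.pgc_mean == pytest.approx(95.0)
        mean = sum(vals) / 3
        sd = (sum((v - mean) ** 2 for v in vals) / 2) ** 0.5  # sample SD
        assert s.pgc_sd == pytest.approx(sd)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
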