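import numpy as np
import pytest

from thermaseg.core import RadiometricMeta, SegmentationError, Thermogram
from thermaseg.phantom import iou
from thermaseg.pipeline import analyze
from thermaseg.preprocessing import BodyMask, extract_body_mask
from thermaseg.segmentation import (
    Polynomial2,
    detect_fold_candidates,
    find_armpit_points,
    fit_fold_polynomial,
    intersect_folds,
    secant_slopes,
    segment_breasts,
)

META = RadiometricMeta(t_min_c=22.0, t_max_c=36.0)


class TestFitFoldPolynomial:
    def test_exact_interpolation(self):
        x = np.arange(10.0)
        pts = np.column_stack([x, 1 + 2 * x + 3 * x**2])
        p = fit_fold_polynomial(pts)
        assert p.coeffs == pytest.approx((1.0, 2.0, 3.0), abs=1e-9)
        assert p.rms == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_matches_normal_equations(self, rng):
        x = np.linspace(0, 20, 50)
        y = 5 - 0.3 * x + 0.1 * x**2 + rng.normal(0, 1, 50)
        p = fit_fold_polynomial(np.column_stack([x, y]))
        design = np.column_stack([np.ones_like(x), x, x * x])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert p.coeffs == pytest.approx(tuple(oracle), abs=1e-6)

    def test_three_points_fit_exactly(self):
        pts = np.array([[0.0, 1.0], [1.0, 4.0], [3.0, 2.0]])
        p = fit_fold_polynomial(pts)
        assert p(pts[:, 0]) == pytest.approx(pts[:, 1], abs=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_fold_polynomial(np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 5.0]]))


class TestIntersectFolds:
    def test_symmetric_parabolas_cross_at_midline(self):
        p1 = Polynomial2(0, 0, 1)            # y = x^2
        p2 = Polynomial2(100, -20, 1)        # y = (x-10)^2
        sp = intersect_folds(p1, p2, (0.0, 10.0))
        assert sp.x == pytest.approx(5.0)
        assert sp.y == pytest.approx(25.0)
        assert not sp.low_confidence

    def test_identical_polynomials_fall_back(self):
        p = Polynomial2(1.0, 2.0, 3.0)
        sp = intersect_folds(p, p, (0.0, 10.0))
        assert sp.low_confidence

    def test_matches_grid_scan_oracle(self, rng):
        for _ in range(20):
            a = Polynomial2(*rng.uniform(-5, 5, 3))
            b = Polynomial2(*rng.uniform(-5, 5, 3))
            lo, hi = 0.0, 50.0
            xs = np.linspace(lo, hi, 200001)
            gap = np.abs(a(xs) - b(xs))
            if gap.min() > 1e-3:
                continue  # no in-range crossing: fallback case
            sp = intersect_folds(a, b, (lo, hi))
            if sp.low_confidence:
                continue
            # the returned root must be (one of) the grid-scan crossings
            assert gap[np.argmin(np.abs(xs - sp.x))] < 1e-2


class TestArmpitDetection:
    @staticmethod
    def _notched_silhouette(notch_row=40, arm_hw=60, torso_hw=40, shape=(120, 160)):
        """Binary raised-arm silhouette with a crisp notch at a known row."""
        H, W = shape
        yy, xx = np.mgrid[0:H, 0:W]
        cx = W / 2
        dx = np.abs(xx - cx)
        ramp = np.clip((yy - notch_row) / 4.0, 0, 1)
        w = arm_hw + ramp * (torso_hw - arm_hw)
        torso = (yy >= notch_row) & (dx <= w)
        arms = (yy <= notch_row) & (dx <= arm_hw) & (dx >= arm_hw - 18)
        neck = dx <= 12
        return BodyMask(torso | arms | neck)

    def test_two_point_slope_exact_on_linear_contour(self):
        f = 2.0 * np.arange(40)
        assert secant_slopes(f, h=10) == pytest.approx(2.0)

    def test_notch_found_within_3_px(self):
        body = self._notched_silhouette(notch_row=40)
        ap = find_armpit_points(body, fold_y=90, h=10)
        for x, y in (ap.right, ap.left):
            assert abs(y - 40) <= 3

    def test_straight_contour_has_no_break(self):
        mask = np.zeros((100, 60), bool)
        mask[5:95, 15:45] = True  # plain rectangle: vertical lateral contours
        with pytest.raises(SegmentationError):
            find_armpit_points(BodyMask(mask), fold_y=90, h=10)

    def test_short_contour_rejected(self):
        body = self._notched_silhouette()
        with pytest.raises(SegmentationError):
            find_armpit_points(body, fold_y=12, h=10)


class TestFoldCandidates:
    def test_ridge_points_track_phantom_crests(self, symmetric_phantom):
        _, tg, _, truth = symmetric_phantom
        body = extract_body_mask(tg)
        ev = detect_fold_candidates(tg, body)
        for side, pts in (("right", ev.ridge_points_right), ("left", ev.ridge_points_left)):
            crest = {x: y for x, y in truth.ridge_curves[side]}
            d = [y - crest[x] for x, y in pts if x in crest]
            assert len(d) > 20
            assert np.sqrt(np.mean(np.square(d))) <= 2.0

    def test_ridge_points_inside_body(self, symmetric_phantom):
        _, tg, _, _ = symmetric_phantom
        body = extract_body_mask(tg)
        ev = detect_fold_candidates(tg, body)
        for pts in (ev.ridge_points_right, ev.ridge_points_left):
            for x, y in pts:
                assert body.mask[int(y), int(x)]

    def test_excessive_offset_rejected(self, symmetric_phantom):
        _, tg, _, _ = symmetric_phantom
        body = extract_body_mask(tg)
        with pytest.raises(SegmentationError):
            detect_fold_candidates(tg, body, offset=255)

    def test_thick_fold_beats_thin_hot_line(self):
        # a 1-px hot line and a thick hot band in the same half: the distance
        # transform ranks the band (larger interior distance) as the fold
        px = np.full((100, 120), 30)
        px[10:95, 10:110] = 180                  # body
        px[20, 20:50] = 250                      # thin hot line
        px[60:69, 15:55] = 250                   # thick hot band
        px[60:69, 65:105] = 250                  # mirror band, other half
        tg = Thermogram(px, META)
        body = extract_body_mask(tg)
        ev = detect_fold_candidates(tg, body, offset=10)
        ys = ev.ridge_points_right[:, 1]
        assert np.all(ys >= 55)  # points on the band, none from the thin line


class TestBreastAssembly:
    def test_phantom_masks_recovered(self, lesion_phantom):
        _, tg, _, truth = lesion_phantom
        body = extract_body_mask(tg)
        seg = segment_breasts(tg, body)
        assert iou(seg.left_mask, truth.left_breast_mask) >= 0.70
        assert iou(seg.right_mask, truth.right_breast_mask) >= 0.70

    def test_masks_disjoint_and_inside_body(self, lesion_phantom):
        _, tg, _, _ = lesion_phantom
        body = extract_body_mask(tg)
        seg = segment_breasts(tg, body)
        assert not (seg.left_mask & seg.right_mask).any()
        assert not (seg.left_mask & ~body.mask).any()
        assert not (seg.right_mask & ~body.mask).any()
        sx = seg.split_point.x
        assert np.nonzero(seg.right_mask)[1].max() < sx
        assert np.nonzero(seg.left_mask)[1].min() > sx

    def test_symmetric_phantom_sides_balance(self, symmetric_phantom):
        _, tg, _, _ = symmetric_phantom
        seg = segment_breasts(tg, extract_body_mask(tg))
        nl, nr = seg.left_mask.sum(), seg.right_mask.sum()
        assert abs(nl - nr) / max(nl, nr) <= 0.05

    def test_masks_cover_lesion_center(self, lesion_phantom):
        spec, tg, _, _ = lesion_phantom
        seg = segment_breasts(tg, extract_body_mask(tg))
        lx, ly = spec.lesion.center
        assert (seg.left_mask | seg.right_mask)[int(ly), int(lx)]

    def test_mirroring_swaps_sides_exactly(self, lesion_phantom):
        _, tg, _, _ = lesion_phantom
        mirrored = Thermogram(tg.pixels[:, ::-1].copy(), tg.meta)
        seg = analyze(tg).segmentation
        seg_m = analyze(mirrored).segmentation
        assert np.array_equal(seg.left_mask, seg_m.right_mask[:, ::-1])
        assert np.array_equal(seg.right_mask, seg_m.left_mask[:, ::-1])
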