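import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import ConvexHull

from ciliametry import DetectionParams, detect_cilia, synth_cilia_image
from ciliametry.cilia import (Contour, canny_thresholds, extract_cilia_contours,
                              filter_cilia_contours, finalize_angle,
                              gaussian_kernel_1d, locate_base, measure_cilium,
                              preprocess, _binary_foreground)
from ciliametry.circular import circular_diff
from ciliametry.io import Image2D

from conftest import make_bar_image, rect_contour


# ---------------------------------------------------------------- preprocess

class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = Image2D(np.full((32, 32), 77.0), 0.5)
        out = preprocess(img)
        assert np.allclose(out.pixels, 77.0)

    def test_output_shape_equals_input(self, bar_image):
        assert preprocess(bar_image).shape == bar_image.shape

    def test_impulse_matches_direct_convolution_oracle(self):
        px = np.zeros((21, 21))
        px[10, 10] = 1.0
        out = preprocess(Image2D(px, 1.0), DetectionParams(gaussian_blur_kernel=3))
        k1 = gaussian_kernel_1d(3)
        kernel2d = np.outer(k1, k1)
        # independent direct convolution oracle (impulse far from borders)
        oracle = np.zeros_like(px)
        for di in range(-1, 2):
            for dj in range(-1, 2):
                oracle[10 + di, 10 + dj] = kernel2d[1 + di, 1 + dj]
        assert np.allclose(out.pixels, oracle, atol=1e-12)

    def test_total_intensity_conserved_away_from_borders(self, rng):
        px = np.zeros((64, 64))
        px[20:44, 20:44] = rng.uniform(0, 255, size=(24, 24))
        out = preprocess(Image2D(px, 1.0))
        assert out.pixels.sum() == pytest.approx(px.sum(), rel=1e-9)


# ------------------------------------------------------- contour extraction

class TestExtractContours:
    def test_median_90_gives_lower_threshold_60_3(self):
        px = np.full((32, 32), 90.0)
        low, high = canny_thresholds(px)
        assert low == pytest.approx(60.3)
        assert high == pytest.approx(119.7)

    def test_all_zero_image_gives_no_contours(self):
        img = Image2D(np.zeros((64, 64)), 0.5)
        assert extract_cilia_contours(img) == []

    def test_single_bar_gives_one_contour_vs_component_oracle(self, bar_image):
        blurred = preprocess(bar_image)
        contours = extract_cilia_contours(blurred)
        binary = _binary_foreground(np.asarray(blurred.pixels), DetectionParams())
        _, n_components = ndimage.label(binary, structure=np.ones((3, 3), int))
        assert len(contours) == n_components == 1

    def test_contour_count_matches_components_on_multi_blob(self):
        px = np.zeros((128, 128), np.uint8)
        px[10:14, 10:40] = 200
        px[60:64, 20:70] = 200
        px[100:104, 80:120] = 200
        blurred = preprocess(Image2D(px, 0.5))
        contours = extract_cilia_contours(blurred)
        binary = _binary_foreground(np.asarray(blurred.pixels), DetectionParams())
        _, n_components = ndimage.label(binary, structure=np.ones((3, 3), int))
        assert len(contours) == n_components == 3

    def test_border_contour_dropping_flag(self):
        px = np.zeros((64, 64), np.uint8)
        px[0:4, 0:30] = 200   # touches top/left border
        px[30:34, 20:50] = 200
        blurred = preprocess(Image2D(px, 0.5))
        keep_all = extract_cilia_contours(blurred)
        dropped = extract_cilia_contours(blurred, DetectionParams(drop_border_contours=True))
        assert len(dropped) < len(keep_all)


# ------------------------------------------------------------- measurement

def _calipers_oracle(points):
    """Brute-force min-area rectangle: one side is collinear with a hull edge."""
    hull = ConvexHull(points)
    verts = points[hull.vertices]
    best = None
    for i in range(len(verts)):
        e = verts[(i + 1) % len(verts)] - verts[i]
        theta = math.atan2(e[1], e[0])
        c, s = math.cos(-theta), math.sin(-theta)
        rot = points @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    return best[1], best[2]


class TestMeasureCilium:
    def test_axis_aligned_20x4_blob(self):
        c = rect_contour(20.0, 4.0)
        length, width, angle = measure_cilium(c, pixel_size_um=0.5)
        assert length == pytest.approx(10.0)
        assert width == pytest.approx(2.0)
        assert angle == pytest.approx(0.0) or angle == pytest.approx(180.0)

    def test_rotated_blob_against_calipers_oracle(self):
        base = np.array([[0, 0], [20, 0], [20, 4], [0, 4]], float)
        theta = math.radians(45)
        c, s = math.cos(theta), math.sin(theta)
        # +45 deg math rotation expressed in image coords (y down)
        rot = base @ np.array([[c, -s], [s, c]])
        contour = Contour(points=rot + 30.0, filled_rc=np.array([[0, 0], [0, 1], [1, 0]]))
        length, width, angle = measure_cilium(contour, pixel_size_um=0.5)
        o_long, o_short = _calipers_oracle(rot)
        assert length == pytest.approx(o_long * 0.5, rel=0.02)
        assert width == pytest.approx(o_short * 0.5, rel=0.02)
        assert circular_diff(angle % 180, 45.0) < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_point_clouds_match_calipers_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(12, 2))
        contour = Contour(points=pts, filled_rc=np.array([[0, 0], [0, 1], [1, 0]]))
        length, width, _ = measure_cilium(contour, pixel_size_um=1.0)
        o_long, o_short = _calipers_oracle(pts)
        assert length == pytest.approx(o_long, rel=1e-6)
        assert width == pytest.approx(o_short, rel=1e-6)

    def test_square_blob_aspect_one(self):
        c = rect_contour(8.0, 8.0)
        length, width, _ = measure_cilium(c, pixel_size_um=1.0)
        assert length == pytest.approx(width)

    def test_degenerate_collinear_contour_flagged_width_zero(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]])
        c = Contour(points=pts, filled_rc=np.array([[0, 0], [5, 5], [10, 10]]))
        length, width, angle = measure_cilium(c, pixel_size_um=1.0)
        assert width == 0.0
        assert length == pytest.approx(math.hypot(10, 10))

    def test_axis_aligned_mode(self):
        c = rect_contour(20.0, 4.0)
        length, width, angle = measure_cilium(
            c, 1.0, DetectionParams(axis_aligned_box=True))
        assert (length, width, angle) == (pytest.approx(20.0), pytest.approx(4.0), 0.0)


# ---------------------------------------------------------------- filtering

class TestFilterContours:
    PIXEL_SIZE = 0.5

    def _image(self):
        return Image2D(np.zeros((200, 200)), self.PIXEL_SIZE)

    def _contour(self, length_um, aspect):
        length_px = length_um / self.PIXEL_SIZE
        return rect_contour(length_px, length_px / aspect)

    def test_half_micron_contour_removed(self):
        kept = filter_cilia_contours([self._contour(0.5, 3.0)], self._image())
        assert kept == []

    def test_10um_aspect_4_retained(self):
        c = self._contour(10.0, 4.0)
        assert filter_cilia_contours([c], self._image()) == [c]

    def test_10um_aspect_1_2_removed(self):
        assert filter_cilia_contours([self._contour(10.0, 1.2)], self._image()) == []

    def test_16um_contour_removed(self):
        assert filter_cilia_contours([self._contour(16.0, 4.0)], self._image()) == []

    def test_order_preserved(self):
        cs = [self._contour(5.0, 3.0), self._contour(8.0, 2.0), self._contour(3.0, 2.0)]
        assert filter_cilia_contours(cs, self._image()) == cs


# ------------------------------------------------------------------- base

class TestLocateBase:
    def test_bright_end_found(self):
        px = make_bar_image(fg=100)
        px[30:34, 10:13] = 255  # bright base at left end
        img = Image2D(px, 0.5)
        rc = np.array([[r, c] for r in range(30, 34) for c in range(10, 50)])
        contour = Contour(points=np.array([[10.0, 30.0], [49.0, 30.0], [10.0, 33.0]]),
                          filled_rc=rc)
        bx, by = locate_base(contour, img)
        assert bx < 13 and 30 <= by <= 33

    def test_uniform_bar_ties_break_in_raster_order(self):
        rc = np.array([[5, 7], [5, 6], [6, 5], [5, 5]])
        c = Contour(points=np.array([[5.0, 5.0], [7.0, 5.0], [5.0, 6.0]]), filled_rc=rc)
        img = Image2D(np.full((10, 10), 42.0), 1.0)
        assert locate_base(c, img) == (5, 5)  # smallest row, then column

    def test_base_inside_contour_mask(self, rng):
        img, scene = synth_cilia_image(5, image_shape=(256, 256), seed=7)
        blurred = preprocess(img)
        for c in extract_cilia_contours(blurred):
            bx, by = locate_base(c, blurred)
            assert any((r == by and col == bx) for r, col in c.filled_rc)


# ------------------------------------------------------------- final angle

class TestFinalizeAngle:
    def test_horizontal_bar_base_left_right_hemisphere(self):
        assert finalize_angle(0.0, (0, 10), (20, 10), "right") == pytest.approx(0.0)

    def test_horizontal_bar_base_right_right_hemisphere(self):
        assert finalize_angle(0.0, (20, 10), (0, 10), "right") == pytest.approx(180.0)

    def test_atan2_oracle_3_4_5(self):
        # base (0,0), centroid at math direction (3,4) -> image coords (3,-4)
        raw = math.degrees(math.atan2(4, 3))  # axis along base->centroid
        got = finalize_angle(raw, (0.0, 0.0), (3.0, -4.0), "right")
        assert got == pytest.approx(math.degrees(math.atan2(4, 3)), abs=1e-9)
        assert got == pytest.approx(53.13, abs=0.01)

    def test_left_hemisphere_mirrors(self):
        raw = math.degrees(math.atan2(4, 3))
        got = finalize_angle(raw, (0.0, 0.0), (3.0, -4.0), "left")
        assert got == pytest.approx(126.87, abs=0.01)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_atan2_oracle_when_axis_aligned_with_offset(self, seed):
        rng = np.random.default_rng(seed)
        dx, dy = rng.uniform(-10, 10, 2)
        if abs(dx) < 1e-6 and abs(dy) < 1e-6:
            dx = 1.0
        expected = math.degrees(math.atan2(-dy, dx)) % 360  # math convention
        raw = expected % 180.0
        got = finalize_angle(raw, (0.0, 0.0), (dx, dy), "right")
        assert circular_diff(got, expected) < 1e-9

    def test_base_equals_centroid_raises(self):
        with pytest.raises(ValueError):
            finalize_angle(10.0, (5.0, 5.0), (5.0, 5.0), "right")

    def test_result_in_range(self, rng):
        for _ in range(200):
            raw = rng.uniform(0, 180)
            b = rng.uniform(0, 50, 2)
            c = rng.uniform(0, 50, 2)
            if np.allclose(b, c):
                continue
            for hemi in ("left", "right"):
                a = finalize_angle(raw, tuple(b), tuple(c), hemi)
                assert 0 <= a < 360


# ---------------------------------------------------------------- pipeline

class TestDetectCilia:
    def test_blank_image_gives_no_records(self):
        img = Image2D(np.zeros((256, 256), np.uint8), 0.5, "right", "ADCY3")
        assert detect_cilia(img) == []

    def test_five_separated_cilia_detected(self):
        img, scene = synth_cilia_image(5, image_shape=(512, 512), seed=11,
                                       length_range_um=(5, 10))
        records = detect_cilia(img)
        assert len(records) == 5

    def test_filter_soundness_of_emitted_records(self):
        img, _ = synth_cilia_image(15, seed=2)
        for r in detect_cilia(img):
            assert 1.0 <= r.length_um <= 15.0
            assert r.length_um / r.width_um >= 1.5
            assert 0 <= r.angle_deg < 360

    def test_determinism(self):
        img, _ = synth_cilia_image(10, image_shape=(512, 512), seed=5)
        r1 = detect_cilia(img)
        r2 = detect_cilia(img)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert a == b

    def test_rotation_consistency_90_degrees(self):
        img, scene = synth_cilia_image(8, image_shape=(512, 512), seed=3,
                                       length_range_um=(5, 10))
        recs = detect_cilia(img)
        rot_img = Image2D(np.rot90(img.pixels).copy(), img.pixel_size_um,
                          img.hemisphere, img.channel)
        rot_recs = detect_cilia(rot_img)
        h, w = img.shape
        matched = 0
        for r in recs:
            bx, by = r.base_xy
            nbx, nby = by, w - 1 - bx  # base position after rot90
            cands = [s for s in rot_recs
                     if math.hypot(s.base_xy[0] - nbx, s.base_xy[1] - nby) < 5]
            if not cands:
                continue
            matched += 1
            assert circular_diff(cands[0].angle_deg, (r.angle_deg + 90) % 360) < 3.0
        assert matched >= 6

    def test_scale_consistency_lengths_double_exactly(self):
        img, _ = synth_cilia_image(6, image_shape=(512, 512), seed=9,
                                   length_range_um=(4, 6), pixel_size_um=0.5)
        r1 = detect_cilia(img)
        img2 = Image2D(img.pixels, 1.0, img.hemisphere, img.channel)
        r2 = detect_cilia(img2)
        assert len(r1) == len(r2) > 0
        for a, b in zip(r1, r2):
            assert b.length_um == pytest.approx(2.0 * a.length_um, abs=1e-12)

    def test_hemisphere_mirroring(self):
        img, _ = synth_cilia_image(6, image_shape=(512, 512), seed=13)
        right = detect_cilia(img)
        left_img = Image2D(img.pixels, img.pixel_size_um, "left", img.channel)
        left = detect_cilia(left_img)
        assert len(right) == len(left) > 0
        for r, l in zip(right, left):
            assert l.angle_deg == pytest.approx((180.0 - r.angle_deg) % 360.0, abs=1e-9)


class TestDetectionParams:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(min_length_um=15, max_length_um=1)
        with pytest.raises(ValueError):
            DetectionParams(min_aspect=0.5)
        with pytest.raises(ValueError):
            DetectionParams(gaussian_blur_kernel=4)
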