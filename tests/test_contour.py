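"""Edge detection, polynomial gap completion and motion decomposition."""

import numpy as np
import pytest
from scipy.special import expit

from oculopulse import (
    ContourSet,
    complete_contour,
    decompose_response,
    detect_corneal_edge,
    median_filter_frame,
)
from oculopulse.exceptions import ContourRejectedError


def band_image(y_rows, thickness=27.0, shape=(200, 576), edge_width=0.7, bg=20.0, fg=180.0):
    """Bright horizontal band whose (sub-pixel) top edge sits at ``y_rows``."""
    y_rows = np.broadcast_to(np.asarray(y_rows, dtype=float), (shape[1],))
    m = np.arange(shape[0], dtype=float)[:, None]
    return bg + (fg - bg) * (expit((m - y_rows) / edge_width) - expit((m - y_rows - thickness) / edge_width))


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 30), 7.0)
        assert np.array_equal(median_filter_frame(img), img)

    def test_isolated_hot_pixel_removed(self):
        img = np.full((20, 30), 10.0)
        img[10, 15] = 250.0
        assert median_filter_frame(img)[10, 15] == 10.0

    def test_center_of_ranked_patch_is_median(self):
        """3x3 patch holding 1..9: the centre becomes 5, the median."""
        img = np.arange(1.0, 10.0).reshape(3, 3)
        assert median_filter_frame(img)[1, 1] == 5.0


class TestEdgeDetection:
    def test_straight_band_edge_recovered_subpixel(self):
        rows, valid = detect_corneal_edge(band_image(100.0))
        inner = slice(5, -5)  # canny masks the image border
        assert valid[inner].all()
        assert np.all(np.abs(rows[inner] - 100.0) < 0.5)

    def test_occluded_columns_flagged_invalid(self):
        img = band_image(100.0)
        img[:, 200:230] = 20.0  # 30-column occlusion
        rows, valid = detect_corneal_edge(img)
        assert not valid[205:225].any()
        assert valid[50:150].all()

    def test_blank_frame_has_no_edges(self):
        rows, valid = detect_corneal_edge(np.full((200, 576), 20.0))
        assert not valid.any()

    def test_noisy_render_mean_error_below_one_pixel(self, rendered, noiseless_extracted):
        """At default render noise the detected resting contour stays within
        1 px (mean absolute error) of the known parabolic geometry."""
        seq, truth = rendered
        rows, valid = detect_corneal_edge(median_filter_frame(seq.frames[0]))
        x_mm = (np.arange(576) - 575 / 2) * 0.02
        truth_rows = 40.0 + (x_mm**2 / (2 * 7.8)) / 0.02
        err = np.abs(rows[valid] - truth_rows[valid])
        assert err.mean() <= 1.0


class TestCompleteContour:
    def test_in_class_polynomial_gap_filled_exactly(self):
        cols = np.arange(576, dtype=float)
        u = (cols - 288) / 288
        rows = 100 + 30 * u**2 - 5 * u**3 + 2 * u**5
        valid = np.ones(576, dtype=bool)
        valid[250:330] = False
        y, _, fill = complete_contour(np.where(valid, rows, np.nan), valid)
        assert fill[250:330].all() and not fill[~np.isnan(rows)][:250].any()
        assert np.allclose(y, rows, atol=1e-6)

    def test_parabola_central_gap_within_tenth_pixel(self):
        cols = np.arange(576, dtype=float)
        rows = 60 + (cols - 288) ** 2 / 500.0
        valid = np.ones(576, dtype=bool)
        valid[240:336] = False
        y, _, _ = complete_contour(np.where(valid, rows, np.nan), valid)
        assert np.max(np.abs(y - rows)) < 0.1

    def test_too_few_valid_columns_rejected(self):
        valid = np.zeros(576, dtype=bool)
        valid[:11] = True
        with pytest.raises(ContourRejectedError):
            complete_contour(np.where(valid, 100.0, np.nan), valid)

    def test_narrow_span_rejected(self):
        valid = np.zeros(576, dtype=bool)
        valid[100:200] = True
        with pytest.raises(ContourRejectedError):
            complete_contour(np.where(valid, 100.0, np.nan), valid)

    def test_completion_is_idempotent(self):
        cols = np.arange(576, dtype=float)
        rows = 80 + 0.0002 * (cols - 288) ** 2
        valid = np.ones(576, dtype=bool)
        valid[100:160] = False
        y1, v1, _ = complete_contour(np.where(valid, rows, np.nan), valid)
        y2, _, f2 = complete_contour(y1, np.ones(576, dtype=bool))
        assert np.array_equal(y1, y2) and not f2.any()


def contour_set(y_frames):
    y = np.asarray(y_frames, dtype=float)
    return ContourSet(
        y=y,
        valid=np.ones_like(y, dtype=bool),
        filled=np.zeros_like(y, dtype=bool),
        frame_valid=np.ones(y.shape[0], dtype=bool),
    )


class TestDecomposition:
    rest = 60 + (np.arange(576) - 288) ** 2 / 800.0

    def test_rigid_shift_goes_entirely_into_eye_motion(self):
        """A 0.2 mm whole-contour shift: eye motion 0.2 mm, reaction ~0."""
        shift_px = 0.2 * 1000 / 20.0
        cs = contour_set([self.rest, self.rest + shift_px])
        dec = decompose_response(cs)
        assert dec.eye_motion_mm[1] == pytest.approx(0.2, abs=1e-9)
        assert np.allclose(dec.corneal_reaction_mm[1], 0.0, atol=1e-9)

    def test_central_indentation_leaves_periphery_still(self):
        bump = 30.0 * np.exp(-((np.arange(576) - 288) ** 2) / (2 * 40.0**2))
        cs = contour_set([self.rest, self.rest + bump])
        dec = decompose_response(cs)
        assert abs(dec.eye_motion_mm[1]) < 0.005
        assert dec.corneal_reaction_mm[1, 288] == pytest.approx(30 * 0.02, abs=0.005)

    def test_reference_frame_decomposes_to_zero(self):
        cs = contour_set([self.rest, self.rest + 3.0])
        dec = decompose_response(cs)
        assert dec.eye_motion_mm[0] == 0.0
        assert np.allclose(dec.corneal_reaction_mm[0], 0.0)

    def test_additivity_of_constant_shift(self):
        """Adding a constant shift to every frame moves eye motion by exactly
        that amount and leaves the corneal reaction untouched."""
        bump = 10.0 * np.exp(-((np.arange(576) - 288) ** 2) / (2 * 50.0**2))
        frames = [self.rest, self.rest + bump, self.rest + 2 * bump]
        base = decompose_response(contour_set(frames))
        shifted = decompose_response(contour_set([f + 7.5 for f in frames]))
        # frame 0 is the rest reference in both stacks, so motions agree
        assert np.allclose(shifted.eye_motion_mm, base.eye_motion_mm, atol=1e-9)
        assert np.allclose(shifted.corneal_reaction_mm, base.corneal_reaction_mm, atol=1e-9)

    def test_invalid_reference_frame_is_fatal(self):
        cs = contour_set([self.rest, self.rest])
        cs.frame_valid[0] = False
        with pytest.raises(ContourRejectedError):
            decompose_response(cs)
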