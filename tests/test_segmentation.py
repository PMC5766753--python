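"""Colour conversion, marker learning and nearest-neighbour classification."""

import numpy as np
import pytest
from conftest import brute_force_classify, srgb_to_lab_oracle

from fpquant import (
    ColourMarker,
    ReanalysisSpec,
    RoiSpec,
    TissueClass,
    classify_pixels,
    learn_markers,
    reanalyze_region,
    rgb_to_lab,
)

F, FI, B, BG = (
    TissueClass.FUNGIFORM,
    TissueClass.FILIFORM,
    TissueClass.BASE,
    TissueClass.BACKGROUND,
)


def _lab_of(rgb):
    return rgb_to_lab(np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3))[0, 0]


class TestRgbToLab:
    @pytest.mark.parametrize(
        "rgb,expected,tol",
        [
            ((255, 255, 255), (100.0, 0.0, 0.0), 0.1),   # white reference
            ((0, 0, 0), (0.0, 0.0, 0.0), 0.1),           # black point
            ((255, 0, 0), (53.24, 80.09, 67.20), 0.5),   # primary red
        ],
    )
    def test_reference_colours(self, rgb, expected, tol):
        lab = _lab_of(rgb)
        assert np.allclose(lab, expected, atol=tol)

    def test_matches_closed_form_chain(self):
        """Conversion agrees with an independent sRGB→XYZ(D65)→CIELAB chain."""
        rng = np.random.default_rng(11)
        for rgb in rng.integers(0, 256, size=(25, 3)):
            lab = _lab_of(rgb)
            assert np.allclose(lab, srgb_to_lab_oracle(rgb), atol=0.05)

    def test_shape_preserved_and_l_range(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(7, 9, 3), dtype=np.uint8)
        lab = rgb_to_lab(img)
        assert lab.shape == (7, 9, 3)
        assert lab[..., 0].min() >= -1e-6 and lab[..., 0].max() <= 100 + 1e-6

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((4, 4, 4), dtype=np.uint8))


class TestLearnMarkers:
    def test_mean_of_constant_roi(self):
        lab = np.tile(np.array([60.0, 25.0, 15.0]), (5, 5, 1))
        rois = [
            RoiSpec(F, np.array([0, 0, 5, 5])),
            RoiSpec(FI, np.array([0, 0, 1, 1])),
            RoiSpec(B, np.array([4, 4, 1, 1])),
        ]
        markers = {m.class_label: m for m in learn_markers(lab, rois)}
        assert np.allclose(markers[F].mean_lab, (60, 25, 15))
        assert markers[F].n_pixels == 25

    def test_arithmetic_mean_of_two_pixels(self):
        lab = np.zeros((1, 2, 3))
        lab[0, 0] = (50, 10, 10)
        lab[0, 1] = (60, 20, 30)
        m = learn_markers(lab, [RoiSpec(F, np.array([0, 0, 2, 1]))], required=(F,))
        assert np.allclose(m[0].mean_lab, (55, 15, 20))

    def test_multiple_rois_pooled_unweighted(self):
        lab = np.zeros((2, 3, 3))
        lab[0, :2] = (10, 0, 0)   # 2 px
        lab[1, 0] = (40, 0, 0)    # 1 px
        rois = [
            RoiSpec(F, np.array([0, 0, 2, 1])),
            RoiSpec(F, np.array([0, 1, 1, 1])),
        ]
        m = learn_markers(lab, rois, required=(F,))[0]
        assert m.n_pixels == 3
        assert np.isclose(m.mean_lab[0], (10 + 10 + 40) / 3)

    def test_missing_class_raises(self):
        lab = np.zeros((4, 4, 3))
        with pytest.raises(ValueError, match="FILIFORM"):
            learn_markers(lab, [RoiSpec(F, np.array([0, 0, 2, 2])),
                                RoiSpec(B, np.array([2, 2, 2, 2]))])

    def test_polygon_roi(self):
        lab = np.zeros((10, 10, 3))
        lab[2:8, 2:8] = (30, 5, 5)
        poly = np.array([[2, 2], [7, 2], [7, 7], [2, 7]], dtype=float)
        m = learn_markers(lab, [RoiSpec(F, poly)], required=(F,))[0]
        assert np.isclose(m.mean_lab[0], 30.0)

    def test_synthetic_base_patch_recovers_generator_colour(self, small_tongue):
        """An ROI on a uniform base patch recovers the true base colour."""
        img, truth, _ = small_tongue
        base = truth.class_map == int(B)
        # a pixel region of pure base tissue near the mask centroid
        rows, cols = np.nonzero(base)
        lab = rgb_to_lab(img)
        m = learn_markers(lab, [RoiSpec(B, base)], required=(B,))[0]
        true_lab = srgb_to_lab_oracle(truth.params.base_rgb)
        # illumination drift averages out over the pooled patch; the learned
        # marker should sit within ~1 CIELAB unit of the rendered base colour
        assert np.linalg.norm(np.asarray(m.mean_lab) - true_lab) < 1.5


class TestClassifyPixels:
    def _markers(self):
        return [
            ColourMarker(F, (50.0, 40.0, 20.0), 1),
            ColourMarker(FI, (85.0, 5.0, 10.0), 1),
            ColourMarker(B, (70.0, 25.0, 12.0), 1),
        ]

    def test_exact_marker_colour_is_zero_distance(self):
        markers = self._markers()
        lab = np.tile(np.array(markers[0].mean_lab), (2, 2, 1))
        assert (classify_pixels(lab, markers) == int(F)).all()

    def test_tie_goes_to_priority_order(self):
        m1 = ColourMarker(F, (10.0, 0.0, 0.0), 1)
        m2 = ColourMarker(B, (30.0, 0.0, 0.0), 1)
        lab = np.tile(np.array([20.0, 0.0, 0.0]), (1, 1, 1))
        # equidistant: FUNGIFORM wins regardless of marker input order
        assert classify_pixels(lab, [m2, m1])[0, 0] == int(F)
        assert classify_pixels(lab, [m1, m2])[0, 0] == int(F)

    def test_matches_brute_force_on_random_images(self):
        """Bit-identical to exhaustive per-pixel nearest-marker search."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            lab = np.stack(
                [
                    rng.uniform(0, 100, (32, 32)),
                    rng.uniform(-60, 60, (32, 32)),
                    rng.uniform(-60, 60, (32, 32)),
                ],
                axis=-1,
            )
            markers = [
                ColourMarker(cls, tuple(rng.uniform(-50, 100, 3)), 1)
                for cls in (F, FI, B)
            ]
            fast = classify_pixels(lab, markers)
            assert np.array_equal(fast, brute_force_classify(lab, markers))

    def test_marker_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        lab = np.stack(
            [rng.uniform(0, 100, (16, 16)),
             rng.uniform(-50, 50, (16, 16)),
             rng.uniform(-50, 50, (16, 16))], axis=-1)
        markers = [
            ColourMarker(cls, tuple(rng.uniform(-40, 90, 3)), 1)
            for cls in (F, FI, B, BG)
        ]
        ref = classify_pixels(lab, markers)
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            assert np.array_equal(ref, classify_pixels(lab, [markers[i] for i in perm]))

    def test_analysis_mask_forces_background(self):
        markers = self._markers()
        lab = np.tile(np.array(markers[0].mean_lab), (4, 4, 1))
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        cmap = classify_pixels(lab, markers, analysis_mask=mask)
        assert (cmap[:2] == int(F)).all()
        assert (cmap[2:] == int(BG)).all()

    def test_completeness_and_exclusivity(self):
        rng = np.random.default_rng(5)
        lab = rng.uniform(-10, 90, (20, 20, 3))
        cmap = classify_pixels(lab, self._markers())
        values, counts = np.unique(cmap, return_counts=True)
        assert set(values) <= {int(F), int(FI), int(B), int(BG)}
        assert counts.sum() == 400

    def test_ab_only_distance_ignores_lightness(self):
        m_dark = ColourMarker(F, (20.0, 30.0, 10.0), 1)
        m_light = ColourMarker(B, (90.0, 0.0, 0.0), 1)
        # pixel: bright but with fungiform chroma
        lab = np.tile(np.array([85.0, 30.0, 10.0]), (1, 1, 1))
        assert classify_pixels(lab, [m_dark, m_light])[0, 0] == int(B)
        assert classify_pixels(lab, [m_dark, m_light], channels="ab")[0, 0] == int(F)

    def test_duplicate_class_labels_rejected(self):
        lab = np.zeros((2, 2, 3))
        ms = [ColourMarker(F, (0.0, 0.0, 0.0), 1), ColourMarker(F, (1.0, 0.0, 0.0), 1)]
        with pytest.raises(ValueError):
            classify_pixels(lab, ms)


class TestReanalyzeRegion:
    def _image_with_shifted_right_half(self):
        """Left half: canonical class colours; right half: shifted shades."""
        rng = np.random.default_rng(13)
        h, w = 40, 60
        lab = np.empty((h, w, 3))
        left_cols = {F: (50, 40, 20), FI: (85, 5, 10), B: (70, 25, 12)}
        right_cols = {F: (40, 55, 28), FI: (75, 15, 18), B: (58, 38, 22)}
        truth = rng.integers(1, 4, size=(h, w)).astype(np.uint8)
        for cls in (F, FI, B):
            m = truth == int(cls)
            lab[m & (np.arange(w)[None, :] < w // 2)] = left_cols[cls]
            lab[m & (np.arange(w)[None, :] >= w // 2)] = right_cols[cls]
        left_rois = [
            RoiSpec(cls, (truth == int(cls)) & (np.arange(w)[None, :] < w // 2))
            for cls in (F, FI, B)
        ]
        return lab, truth, left_rois

    def test_whole_image_rectangle_with_global_markers_is_idempotent(self):
        lab, truth, rois = self._image_with_shifted_right_half()
        markers = learn_markers(lab, rois)
        base = classify_pixels(lab, markers)
        spec = ReanalysisSpec((0, 0, lab.shape[1], lab.shape[0]), local_markers=list(markers))
        assert np.array_equal(reanalyze_region(lab, base, spec), base)

    def test_zero_area_rectangle_is_identity(self):
        lab, truth, rois = self._image_with_shifted_right_half()
        markers = learn_markers(lab, rois)
        base = classify_pixels(lab, markers)
        out = reanalyze_region(lab, base, ReanalysisSpec((5, 5, 0, 0)), global_markers=markers)
        assert np.array_equal(out, base)

    def test_local_markers_fix_colour_drift(self):
        """Re-analysing the shifted half with local ROIs removes all errors
        there while leaving the other half bit-identical."""
        lab, truth, left_rois = self._image_with_shifted_right_half()
        h, w = truth.shape
        markers = learn_markers(lab, left_rois)
        base = classify_pixels(lab, markers)
        assert (base[:, w // 2:] != truth[:, w // 2:]).any()  # drift misclassifies

        right = np.arange(w)[None, :] >= w // 2
        local_rois = [RoiSpec(cls, (truth == int(cls)) & right) for cls in (F, FI, B)]
        spec = ReanalysisSpec((w // 2, 0, w // 2, h), local_rois=local_rois)
        out = reanalyze_region(lab, base, spec, global_markers=markers)
        assert np.array_equal(out[:, : w // 2], base[:, : w // 2])
        assert np.array_equal(out[:, w // 2:], truth[:, w // 2:])

    def test_missing_local_class_falls_back_to_global(self):
        lab, truth, left_rois = self._image_with_shifted_right_half()
        h, w = truth.shape
        markers = learn_markers(lab, left_rois)
        base = classify_pixels(lab, markers)
        right = np.arange(w)[None, :] >= w // 2
        local_rois = [RoiSpec(F, (truth == int(F)) & right)]  # only fungiform
        spec = ReanalysisSpec((w // 2, 0, w // 2, h), local_rois=local_rois)
        out = reanalyze_region(lab, base, spec, global_markers=markers)
        # fungiform pixels in the rectangle are now correct
        assert (out[:, w // 2:][truth[:, w // 2:] == int(F)] == int(F)).all()

    def test_rectangle_outside_image_raises(self):
        lab = np.zeros((10, 10, 3))
        base = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            reanalyze_region(lab, base, ReanalysisSpec((5, 5, 10, 2)))
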