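"""Detection tests: glint handling, enhancement, edges, circle fitting."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pupilkit.detect import (DetectConfig, NoFitError, ROI, crop_roi,
                             detect_glints, enhance, exhaustive_circle_search,
                             fit_iris_circle, fit_pupil_circle, measure_frame,
                             pupil_edges, remove_glints)
from pupilkit.synthetic import EyeSceneSpec, render_eye_frame


class TestCropROI:
    def test_full_frame_is_identity(self, scene):
        img = render_eye_frame(scene, 50.0)
        out = crop_roi(img, ROI(0, 0, *img.shape))
        np.testing.assert_array_equal(out, img)

    def test_offset_crop(self, scene):
        img = render_eye_frame(scene, 50.0)
        out = crop_roi(img, ROI(10, 20, 100, 100))
        assert out.shape == (100, 100)
        assert out[0, 0] == img[10, 20]

    def test_out_of_bounds_rejected(self, scene):
        img = render_eye_frame(scene, 50.0)
        with pytest.raises(ValueError):
            crop_roi(img, ROI(200, 0, 100, 100))


class TestGlints:
    def test_four_components_detected(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        mask = detect_glints(img, config=detect_config)
        _, n = ndi.label(mask)
        assert n == 4

    def test_uniform_image_gives_empty_mask(self, detect_config):
        mask = detect_glints(np.full((64, 64), 80, np.uint8),
                             config=detect_config)
        assert not mask.any()

    def test_component_areas_near_glint_area(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        mask = detect_glints(img, config=detect_config)
        labels, n = ndi.label(mask)
        # rendered glint footprint: every pixel brighter than the iris
        rendered = int((img > scene.iris_gray).sum())
        for i in range(1, n + 1):
            area = int((labels == i).sum())
            assert area >= rendered / 4  # mask must cover the rendered spot
            assert area <= 3.0 * np.pi * scene.glint_radius_px ** 2

    def test_masked_pixels_set_to_35(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        mask = detect_glints(img, config=detect_config)
        out = remove_glints(img, mask, fill_gray=35)
        assert (out[mask] == 35).all()
        np.testing.assert_array_equal(out[~mask], img[~mask])

    def test_pupil_interior_clean_after_removal(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        out = remove_glints(img, detect_glints(img, config=detect_config))
        cy, cx = scene.pupil_center_px
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        inside = np.hypot(yy - cy, xx - cx) < 50.0 - 1.5
        assert out[inside].max() <= 35

    def test_empty_mask_is_noop(self, scene):
        img = render_eye_frame(scene, 50.0)
        out = remove_glints(img, np.zeros_like(img, dtype=bool))
        np.testing.assert_array_equal(out, img)

    def test_shape_mismatch_rejected(self, scene):
        img = render_eye_frame(scene, 50.0)
        with pytest.raises(ValueError):
            remove_glints(img, np.zeros((10, 10), dtype=bool))


class TestEnhance:
    def test_uniform_stays_uniform(self):
        img = np.full((32, 32), 120, np.uint8)
        out = enhance(img)
        assert np.unique(out[2:-2, 2:-2]).size == 1

    def test_gamma_of_half(self):
        # gamma stage alone on r = 0.5: 0.5 ** 0.6 = 0.659754
        assert 0.5 ** 0.6 == pytest.approx(0.659754, abs=1e-6)
        # a uniform image at the level that the high-boost maps to 0.5
        # (A=2: 2v - v = v, so v = 0.5 -> gray 128 rounds through 0.502)
        out = enhance(np.full((16, 16), 128, np.uint8))
        assert out[8, 8] == int(round((128 / 255) ** 0.6 * 255))

    def test_step_edge_gradient_amplified(self):
        img = np.full((32, 32), 60, np.uint8)
        img[:, 16:] = 110
        out = enhance(img).astype(float)
        g_before = np.abs(np.diff(img.astype(float), axis=1)).max() / 255
        g_after = np.abs(np.diff(out, axis=1)).max() / 255
        assert g_after > g_before

    def test_boost_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            enhance(np.zeros((8, 8), np.uint8), boost_factor=1.0)


class TestPupilEdges:
    def _edges(self, scene, radius, config, **scene_kw):
        spec = EyeSceneSpec(pupil_center_px=scene.pupil_center_px,
                            **scene_kw)
        img = render_eye_frame(spec, radius)
        clean = remove_glints(img, detect_glints(img, config=config))
        return pupil_edges(enhance(clean), config=config), spec

    def test_edges_lie_on_true_circle(self, scene, detect_config):
        edges, spec = self._edges(scene, 50.0, detect_config)
        cy, cx = spec.pupil_center_px
        ys, xs = np.nonzero(edges)
        d = np.hypot(ys - cy, xs - cx)
        on_circle = np.abs(d - 50.0) <= 1.5
        # consider only edges in the pupil neighbourhood (not iris rim)
        near = d < 75
        assert on_circle[near].mean() >= 0.9

    def test_uniform_image_has_no_edges(self, detect_config):
        edges = pupil_edges(np.full((64, 64), 90, np.uint8),
                            config=detect_config)
        assert not edges.any()

    def test_occluded_pupil_keeps_lower_arc(self, scene, detect_config):
        edges, spec = self._edges(scene, 60.0, detect_config,
                                  eyelid_coverage_fraction=0.25)
        cy, cx = spec.pupil_center_px
        ys, xs = np.nonzero(edges)
        d = np.hypot(ys - cy, xs - cx)
        ring = np.abs(d - 60.0) <= 1.5
        angles = np.arctan2(ys[ring] - cy, xs[ring] - cx)
        covered = np.unique(np.round(np.degrees(angles))).size / 360.0
        assert covered >= 0.5


class TestCircleFit:
    def _circle_edges(self, shape, cy, cx, r):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        d = np.hypot(yy - cy, xx - cx)
        return np.abs(d - r) < 0.5

    def test_exact_circle_within_search_resolution(self, detect_config):
        edges = self._circle_edges((128, 128), 64.0, 64.0, 43.0)
        fit = fit_pupil_circle(edges, detect_config)
        assert fit.converged
        assert fit.radius_px == pytest.approx(43.0, abs=0.2)

    def test_occluded_circle_within_one_pixel(self, detect_config):
        edges = self._circle_edges((160, 160), 80.0, 80.0, 50.0)
        edges[:55, :] = False  # erase the top quarter of the ring
        fit = fit_pupil_circle(edges, detect_config)
        assert fit.radius_px == pytest.approx(50.0, abs=1.0)

    def test_empty_edges_raise(self, detect_config):
        with pytest.raises(NoFitError):
            fit_pupil_circle(np.zeros((64, 64), bool), detect_config)

    def test_tie_breaks_toward_smaller_radius(self):
        """Exactly tied scores resolve to the smaller candidate radius."""
        from pupilkit.detect import _best_over_maps

        flat = np.full((5, 5), 0.4)
        score, idx, radius = _best_over_maps(lambda r: flat,
                                             [20.0, 20.2, 25.0])
        assert radius == 20.0
        assert idx == (0, 0)  # first row-major cell on a tied map
        assert score == 0.4

    def test_score_peaks_at_truth(self, scene, detect_config):
        """Fit score exceeds the score of displaced circles by >= 2 px."""
        from pupilkit.detect import RingCorrelator

        edges = self._circle_edges((128, 128), 64.0, 64.0, 40.0)
        corr = RingCorrelator(edges.shape, detect_config)
        efft = corr.edges_fft(edges)
        s_true = corr.score_map(efft, 40.0)[64, 64]
        assert s_true > corr.score_map(efft, 42.0).max()
        assert s_true > corr.score_map(efft, 38.0).max()
        smap = corr.score_map(efft, 40.0)
        smap[62:67, 62:67] = -np.inf  # excise the true-center neighbourhood
        assert s_true > smap.max()

    @pytest.mark.parametrize("seed", range(5))
    def test_staged_search_matches_exhaustive(self, seed):
        """Grid-stage result equals brute force over (center x radius)."""
        rng = np.random.default_rng(seed)
        cfg = DetectConfig(radius_min_px=10.0, radius_max_px=28.0,
                           refine_center=False)
        cy, cx = rng.uniform(24, 40, 2)
        r = rng.uniform(12, 26)
        th = np.linspace(0, 2 * np.pi, 400)
        keep = rng.random(400) > 0.15
        ys = np.clip(np.rint(cy + r * np.sin(th[keep])), 0, 63).astype(int)
        xs = np.clip(np.rint(cx + r * np.cos(th[keep])), 0, 63).astype(int)
        edges = np.zeros((64, 64), bool)
        edges[ys, xs] = True
        spur = rng.integers(0, 64, (2, 15))
        edges[spur[0], spur[1]] = True
        a = fit_pupil_circle(edges, cfg)
        b = exhaustive_circle_search(edges, cfg)
        assert a.center_px == b.center_px
        assert a.radius_px == pytest.approx(b.radius_px, abs=1e-9)


class TestIrisFit:
    def test_known_iris_radius(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        clean = remove_glints(img, detect_glints(img, config=detect_config))
        fit = fit_iris_circle(clean, detect_config)
        assert fit.radius_px == pytest.approx(scene.iris_radius_px, abs=1.0)

    def test_no_circle_raises(self, detect_config):
        with pytest.raises(NoFitError):
            fit_iris_circle(np.full((240, 320), 90, np.uint8),
                            detect_config)

    def test_random_scenes_within_two_pixels(self, detect_config):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(10):
            iris_r = float(rng.uniform(100, 120))
            cy = float(rng.uniform(118, 122))
            cx = float(rng.uniform(155, 165))
            spec = EyeSceneSpec(pupil_center_px=(cy, cx),
                                iris_radius_px=iris_r)
            img = render_eye_frame(spec, float(rng.uniform(30, 60)))
            clean = remove_glints(img, detect_glints(img,
                                                     config=detect_config))
            fit = fit_iris_circle(clean, detect_config)
            errs.append(abs(fit.radius_px - iris_r))
        assert max(errs) <= 2.0


class TestMeasureFrame:
    def test_blink_frame_invalid(self, scene, full_roi, detect_config):
        img = render_eye_frame(scene, 50.0, blink=True)
        m = measure_frame(img, full_roi, detect_config)
        assert not m.valid

    def test_clean_frame_subpixel(self, scene, full_roi, detect_config):
        img = render_eye_frame(scene, 60.0)
        m = measure_frame(img, full_roi, detect_config)
        assert m.valid
        assert m.pupil.radius_px == pytest.approx(60.0, abs=0.2)

    def test_roi_offset_applied_to_center(self, scene, detect_config):
        img = render_eye_frame(scene, 50.0)
        roi = ROI(20, 30, 200, 260)
        m = measure_frame(img, roi, detect_config)
        cy, cx = scene.pupil_center_px
        assert m.pupil.center_px[0] == pytest.approx(cy, abs=0.3)
        assert m.pupil.center_px[1] == pytest.approx(cx, abs=0.3)

    def test_sequence_in_frame_order(self, single_flash_measured):
        measurements, iris = single_flash_measured
        assert len(measurements) == 90
        assert [m.frame_index for m in measurements] == list(range(90))
        assert iris is not None
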