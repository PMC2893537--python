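"""Pupillogram tests: assembly, blinks, crossings, parameter extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilkit.detect import CircleFit, FrameMeasurement
from pupilkit.synthetic import (FlashProtocol, PLRModel, flash_train_protocol,
                                generate_ground_truth, healthy_train_model,
                                single_flash_protocol)
from pupilkit.trace import (BlinkReport, ExtractionConfig, PupilTrace,
                            TraceExcludedError, baseline_radius, build_trace,
                            crossing_time, detect_blinks, extract_flash_train,
                            extract_single_flash)


def _measurement(i, radius, fps=30.0, valid=True):
    fit = CircleFit((120.0, 160.0), radius, 0.8) if valid else None
    return FrameMeasurement(frame_index=i, time_s=i / fps, pupil=fit,
                            valid=valid)


def _trace(radii, valid=None, fps=30.0, iris=110.0, protocol=None):
    radii = np.asarray(radii, dtype=float)
    if valid is None:
        valid = np.isfinite(radii)
    if protocol is None:
        protocol = single_flash_protocol()
    return PupilTrace(np.arange(radii.size) / fps, radii,
                      np.asarray(valid, bool), fps, iris, protocol)


def truth_trace(model, protocol, iris=110.0):
    truth = generate_ground_truth(model, protocol)
    return PupilTrace(truth.times_s, truth.radii_px,
                      np.ones(len(truth), bool), protocol.fps, iris,
                      protocol)


class TestBuildTrace:
    def test_time_span(self):
        ms = [_measurement(i, 60.0) for i in range(90)]
        tr = build_trace(ms, 30.0, single_flash_protocol(), 110.0)
        assert len(tr) == 90
        assert tr.times_s[-1] == pytest.approx(89 / 30)

    def test_invalid_frame_kept_as_gap(self):
        ms = [_measurement(i, 60.0, valid=(i != 5)) for i in range(10)]
        tr = build_trace(ms, 30.0, single_flash_protocol(), 110.0)
        assert not tr.valid[5] and np.isnan(tr.radii_px[5])
        assert tr.valid.sum() == 9

    def test_zero_iris_rejected(self):
        ms = [_measurement(i, 60.0) for i in range(10)]
        with pytest.raises(ValueError):
            build_trace(ms, 30.0, single_flash_protocol(), 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_trace([], 30.0, single_flash_protocol(), 110.0)


class TestBlinks:
    def test_four_runs_excluded(self):
        radii = np.full(90, 60.0)
        valid = np.ones(90, bool)
        for s in (10, 30, 50, 70):
            valid[s:s + 3] = False
        report = detect_blinks(_trace(radii, valid))
        assert report.blink_count == 4
        assert report.excluded

    def test_clean_trace_no_blinks(self):
        report = detect_blinks(_trace(np.full(90, 60.0)))
        assert report == BlinkReport((), 0, False)

    def test_single_run_counts_once(self):
        valid = np.ones(90, bool)
        valid[20:25] = False
        report = detect_blinks(_trace(np.full(90, 60.0), valid))
        assert report.blink_count == 1
        assert report.blink_intervals == ((20, 24),)

    def test_radius_jump_flagged_as_blink(self):
        radii = np.full(90, 60.0)
        radii[40:43] = 20.0  # partially-closed lid mismeasurement
        report = detect_blinks(_trace(radii))
        assert report.blink_count >= 1


class TestBaseline:
    def test_frame_preceding_flash(self):
        radii = np.full(60, 59.0)
        radii[29] = 60.0
        tr = _trace(radii, protocol=FlashProtocol((1.0,), 2.0))
        assert baseline_radius(tr, 1.0) == 60.0

    def test_skips_invalid_frame(self):
        radii = np.full(60, 59.0)
        radii[28] = 59.8
        valid = np.ones(60, bool)
        valid[29] = False
        tr = _trace(radii, valid, protocol=FlashProtocol((1.0,), 2.0))
        assert baseline_radius(tr, 1.0) == 59.8

    def test_flash_at_zero_has_no_baseline(self):
        tr = _trace(np.full(60, 60.0), protocol=FlashProtocol((0.0,), 2.0))
        with pytest.raises(ValueError):
            baseline_radius(tr, 0.0)


class TestCrossing:
    def test_linear_interpolation(self):
        # 100 -> 80 linearly over [0, 1] s at 30 fps; level 90 at t = 0.5
        radii = 100.0 - 20.0 * np.arange(31) / 30.0
        tr = _trace(radii)
        t = crossing_time(tr, 90.0, (0.0, 1.0), "down")
        assert t == pytest.approx(0.5, abs=1e-9)

    def test_constant_trace_not_found(self):
        from pupilkit.trace import ParameterNotFound
        tr = _trace(np.full(31, 50.0))
        with pytest.raises(ParameterNotFound):
            crossing_time(tr, 40.0, (0.0, 1.0), "down")

    def test_crossing_at_frame_time_returns_frame_time(self):
        radii = np.array([100.0, 90.0, 80.0, 70.0])
        tr = _trace(radii)
        t = crossing_time(tr, 90.0, (0.0, 0.2), "down")
        assert t == pytest.approx(1 / 30)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_dense_scan_oracle(self, seed):
        """Interpolated crossing agrees with a dense numeric scan."""
        rng = np.random.default_rng(seed)
        radii = np.sort(rng.uniform(40, 60, 20))[::-1].copy()
        level = float(rng.uniform(radii[-1] + 0.1, radii[0] - 0.1))
        tr = _trace(radii)
        t = crossing_time(tr, level, (0.0, radii.size / 30.0), "down")
        # oracle: dense linear interpolation of the whole trace
        tt = np.linspace(0, (radii.size - 1) / 30.0, 20000)
        rr = np.interp(tt, tr.times_s, radii)
        t_oracle = tt[np.argmax(rr < level)]
        assert t == pytest.approx(t_oracle, abs=1e-3)


class TestSingleFlashExtraction:
    def test_recovers_analytic_parameters(self):
        model = PLRModel()  # baseline 60, min 44, flash at 0.5 s
        tr = truth_trace(model, single_flash_protocol())
        p = extract_single_flash(tr)
        # onset: 0.9*60 = 54 on the linear descent 60->44 over [0.7, 1.4]
        assert p.latency_to_constriction_s == pytest.approx(0.4625, abs=1e-6)
        assert p.latency_to_largest_constriction_s == pytest.approx(
            0.9, abs=1 / 30)
        # plateau: 45 = 49.8 - 5.8 exp(-(t - 1.4)/5) -> latency 1.8462 s
        assert p.latency_to_plateau_s == pytest.approx(1.8462, abs=1 / 30)
        assert p.reflex_amplitude_px == pytest.approx(16.0, abs=1e-9)
        assert p.ratio_PI_darkness == pytest.approx(60 / 110)
        assert p.ratio_PI_plateau == pytest.approx(0.75 * 60 / 110)

    def test_flat_trace_has_no_onset(self):
        tr = _trace(np.full(90, 60.0))
        p = extract_single_flash(tr)
        assert p.reflex_amplitude_px == 0.0
        assert p.latency_to_constriction_s is None
        assert p.velocity_of_constriction_px_per_s is None

    def test_velocity_is_amplitude_over_duration(self):
        tr = truth_trace(PLRModel(), single_flash_protocol())
        p = extract_single_flash(tr)
        assert p.velocity_of_constriction_px_per_s == \
            p.reflex_amplitude_px / p.duration_of_constriction_s

    def test_latency_ordering_invariant(self):
        tr = truth_trace(PLRModel(), single_flash_protocol())
        p = extract_single_flash(tr)
        assert (p.latency_to_constriction_s
                <= p.latency_to_largest_constriction_s
                <= p.latency_to_plateau_s)

    def test_ratio_ordering_follows_radius_ordering(self):
        tr = truth_trace(PLRModel(), single_flash_protocol())
        p = extract_single_flash(tr)
        assert (0 < p.ratio_PI_largest_constriction
                <= p.ratio_PI_plateau <= p.ratio_PI_darkness < 1)

    def test_excluded_trace_refused(self):
        radii = np.full(90, 60.0)
        valid = np.ones(90, bool)
        for s in (5, 25, 45, 65):
            valid[s] = False
        tr = _trace(radii, valid)
        with pytest.raises(TraceExcludedError):
            extract_single_flash(tr)

    def test_three_blinks_still_extracted(self):
        tr = truth_trace(PLRModel(), single_flash_protocol())
        valid = tr.valid.copy()
        for s in (3, 8, 80):
            valid[s] = False
        tr2 = PupilTrace(tr.times_s, tr.radii_px, valid, tr.fps,
                         tr.iris_radius_px, tr.protocol)
        p = extract_single_flash(tr2)
        assert p.reflex_amplitude_px == pytest.approx(16.0, abs=1e-9)

    def test_duration_definitions(self):
        tr = truth_trace(PLRModel(), single_flash_protocol())
        to_min = extract_single_flash(
            tr, ExtractionConfig(duration_definition="to_minimum"))
        default = extract_single_flash(tr)
        # descent ends at t = 1.4 s; onset at 0.9625 s
        assert to_min.duration_of_constriction_s == pytest.approx(
            1.4 - 0.9625, abs=1 / 30)
        assert default.duration_of_constriction_s <= \
            to_min.duration_of_constriction_s + 1 / 30


class TestTrainExtraction:
    def test_adapting_train_preflash_radii(self):
        model = healthy_train_model()
        tr = truth_trace(model, flash_train_protocol())
        p = extract_flash_train(tr)
        assert p.pre_1st_radius_px == pytest.approx(60.0, abs=1e-9)
        # steady state 0.55 * 60 = 33, within one frame of recovery dynamics
        assert p.pre_25th_radius_px == pytest.approx(33.0, abs=1.0)
        assert p.pre_10th_radius_px > p.pre_25th_radius_px

    def test_non_adapting_train_constant_baseline(self):
        # tau chosen so redilation stays below the blink-jump rate while
        # still essentially completing within each 1-s window
        model = PLRModel(min_radius_px=42.0, latency_onset_s=0.25,
                         time_to_min_s=0.68, recovery_tau_s=0.06,
                         train_adaptation_fraction=1.0)
        tr = truth_trace(model, flash_train_protocol())
        p = extract_flash_train(tr)
        # identical window dynamics: later pre-flash radii agree exactly
        assert p.pre_25th_radius_px == pytest.approx(p.pre_10th_radius_px,
                                                     abs=1e-9)
        # and match the initial baseline up to the recovery residual
        assert p.pre_10th_radius_px == pytest.approx(p.pre_1st_radius_px,
                                                     abs=0.2)

    def test_per_flash_latencies_below_interval(self):
        tr = truth_trace(healthy_train_model(), flash_train_protocol())
        p = extract_flash_train(tr)
        for lat in (p.latency_to_constriction_10th_s,
                    p.latency_to_largest_constriction_10th_s,
                    p.latency_to_constriction_25th_s,
                    p.latency_to_largest_constriction_25th_s):
            assert lat is not None
            assert 0 <= lat < 1.0

    def test_ratios_in_unit_interval(self):
        tr = truth_trace(healthy_train_model(), flash_train_protocol())
        p = extract_flash_train(tr)
        for v in (p.ratio_PI_pre_1st, p.ratio_PI_pre_10th,
                  p.ratio_PI_pre_25th, p.ratio_PI_min_after_10th,
                  p.ratio_PI_min_after_25th, p.ratio_PI_plateau):
            assert 0 < v < 1
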