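"""Flow quantification: corrections, curves, interval volumes, report metrics."""

import numpy as np
import pytest

import valvepc as v
from valvepc import flow_quant as fq

from conftest import square_roi


def roi_series(poly, n=10, role="mitral"):
    return fq.RoiSeries(role, [poly] * n)


class TestBackgroundCorrect:
    def test_constant_offset_removed_exactly(self, flat_series):
        series = flat_series.copy()
        series.velocity += 2.0
        static = roi_series(square_roi(1, 1, 5, 5), role="static-tissue")
        out = fq.background_correct(series, static)
        np.testing.assert_allclose(out.velocity, flat_series.velocity, atol=1e-12)

    def test_offset_free_series_unchanged(self, flat_series):
        rng = np.random.default_rng(0)
        series = flat_series.copy()
        field = rng.normal(0, 5, flat_series.velocity.shape)
        field -= field[:, 1:6, 1:6].mean(axis=(1, 2))[:, None, None]
        series.velocity = field
        static = roi_series(square_roi(1, 1, 5, 5), role="static-tissue")
        out = fq.background_correct(series, static)
        np.testing.assert_allclose(out.velocity, series.velocity, atol=1e-9)

    def test_empty_static_roi_names_phase(self, flat_series):
        tiny = np.array([[0.1, 0.1], [0.2, 0.1], [0.1, 0.2]])  # encloses no centre
        with pytest.raises(ValueError, match="phase 0"):
            fq.background_correct(flat_series, roi_series(tiny, role="static-tissue"))


class TestMotionCorrect:
    def test_zero_curve_is_identity(self, flat_series):
        out = fq.motion_correct(flat_series, np.zeros(flat_series.n_phases))
        np.testing.assert_array_equal(out.velocity, flat_series.velocity)
        np.testing.assert_array_equal(out.magnitude, flat_series.magnitude)

    def test_self_cancellation(self, flat_series):
        vv = np.linspace(-3, 3, flat_series.n_phases)
        series = flat_series.copy()
        series.velocity += vv[:, None, None]
        out = fq.motion_correct(series, vv)
        roi = roi_series(square_roi(4, 4, 10, 10))
        curve = fq.compute_flow_curve(out, roi, 5)
        np.testing.assert_allclose(curve.net, 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self, flat_series):
        with pytest.raises(ValueError, match="phases"):
            fq.motion_correct(flat_series, np.zeros(3))


class TestComputeFlowCurve:
    def test_uniform_velocity_rate(self, flat_series):
        series = flat_series.copy()
        series.velocity[:] = 10.0  # cm/s over 1 mm² pixels
        curve = fq.compute_flow_curve(series, roi_series(square_roi(5, 5, 14, 14)), 5)
        np.testing.assert_allclose(curve.net, 10.0)  # 100 px -> 10 ml/s
        np.testing.assert_allclose(curve.forward, 10.0)
        np.testing.assert_allclose(curve.backward, 0.0)

    def test_split_field_forward_backward(self, flat_series):
        series = flat_series.copy()
        series.velocity[:, :, :10] = 10.0
        series.velocity[:, :, 10:] = -10.0
        curve = fq.compute_flow_curve(series, roi_series(square_roi(5, 5, 14, 14)), 5)
        np.testing.assert_allclose(curve.net, 0.0, atol=1e-12)
        np.testing.assert_allclose(curve.forward, 5.0)
        np.testing.assert_allclose(curve.backward, -5.0)

    def test_zero_velocity_zero_curve(self, flat_series):
        curve = fq.compute_flow_curve(flat_series, roi_series(square_roi(5, 5, 14, 14)), 5)
        np.testing.assert_allclose(curve.net, 0.0)

    def test_roi_outside_bounds_rejected(self, flat_series):
        with pytest.raises(ValueError, match="bounds"):
            fq.compute_flow_curve(flat_series, roi_series(square_roi(5, 5, 25, 25)), 5)

    def test_curve_invariant_enforced(self):
        with pytest.raises(ValueError, match="forward"):
            fq.FlowCurve(
                net=np.array([1.0]),
                forward=np.array([2.0]),
                backward=np.array([0.5]),
                phase_durations=np.array([100.0]),
                partition=0,
            )


class TestIntegrateInterval:
    def make_curve(self, rates, durations, partition=1):
        rates = np.asarray(rates, float)
        return fq.FlowCurve(
            rates, np.clip(rates, 0, None), np.clip(rates, None, 0),
            np.asarray(durations, float), partition,
        )

    def test_constant_rate(self):
        curve = self.make_curve([10.0, 10.0], [200.0, 200.0])
        assert fq.integrate_interval(curve, (0, 2))[0] == pytest.approx(4.0)

    def test_hand_sum(self):
        curve = self.make_curve([10.0, 20.0], [200.0, 100.0])
        net, fwd, bwd = fq.integrate_interval(curve, (0, 2))
        assert net == pytest.approx(4.0) and fwd == pytest.approx(4.0) and bwd == 0.0

    def test_linearity_net_equals_forward_plus_backward(self):
        rng = np.random.default_rng(4)
        rates = rng.normal(0, 10, 12)
        curve = self.make_curve(rates, np.full(12, 80.0), partition=5)
        net, fwd, bwd = fq.integrate_interval(curve, (3, 9))
        assert net == pytest.approx(fwd + bwd)

    def test_wrapping_range(self):
        curve = self.make_curve([1.0, 2.0, 3.0, 4.0], np.full(4, 1000.0))
        net, _, _ = fq.integrate_interval(curve, (3, 1))  # phases 3 and 0
        assert net == pytest.approx(5.0)

    def test_empty_range_warns_and_returns_zero(self):
        curve = self.make_curve([1.0, 2.0], [100.0, 100.0])
        with pytest.warns(UserWarning, match="empty"):
            assert fq.integrate_interval(curve, (1, 1)) == (0.0, 0.0, 0.0)


def curve_from_volumes(sys_fwd, sys_bwd, dia_fwd, dia_bwd, es=10, n=30, rr=1000.0):
    """Flow curve whose interval volumes match the requested ml values."""
    dt = rr / n
    fwd = np.zeros(n)
    bwd = np.zeros(n)
    fwd[:es] = sys_fwd / (es * dt / 1000.0)
    bwd[:es] = sys_bwd / (es * dt / 1000.0)
    fwd[es:] = dia_fwd / ((n - es) * dt / 1000.0)
    bwd[es:] = dia_bwd / ((n - es) * dt / 1000.0)
    return fq.FlowCurve(fwd + bwd, fwd, bwd, np.full(n, dt), es)


class TestSummarizeVolumes:
    def test_printed_row_additivity(self):
        """Systolic net = forward + backward: 6 + (−11) = −5 ml."""
        curve = curve_from_volumes(6.0, -11.0, 97.0, -6.0)
        report = v.summarize_volumes(curve)
        vols = report.flow_volumes_ml["measured"]["systolic"]
        assert vols["forward"] == pytest.approx(6.0)
        assert vols["backward"] == pytest.approx(-11.0)
        assert vols["net"] == pytest.approx(-5.0)

    def test_regurgitant_volume_three_ways(self):
        mitral = curve_from_volumes(0.5, -10.0, 80.0, -2.0)
        aortic = curve_from_volumes(70.0, 0.0, 0.0, 0.0)
        report = v.summarize_volumes(mitral, aortic, planimetric=(160.0, 80.0))
        assert report.mitral_sv_ml == pytest.approx(80.0)
        assert report.aortic_sv_ml == pytest.approx(70.0)
        assert report.regurgitant_volume_direct_ml == pytest.approx(10.0)
        assert report.regurgitant_volume_mitral_minus_aortic_ml == pytest.approx(10.0)
        assert report.regurgitant_volume_guideline_ml == pytest.approx(10.0)
        assert report.regurgitant_fraction_mitral_pct == pytest.approx(12.5)
        assert report.regurgitant_fraction_planimetric_pct == pytest.approx(12.5)

    def test_missing_planimetry_flags_guideline_only(self):
        mitral = curve_from_volumes(0.0, -10.0, 80.0, 0.0)
        aortic = curve_from_volumes(70.0, 0.0, 0.0, 0.0)
        report = v.summarize_volumes(mitral, aortic)
        assert np.isnan(report.regurgitant_volume_guideline_ml)
        assert np.isnan(report.regurgitant_fraction_planimetric_pct)
        assert report.regurgitant_volume_direct_ml == pytest.approx(10.0)
        assert any("planimetric" in n for n in report.notes)

    def test_static_plane_refuses_direct_regurgitation(self):
        mitral = curve_from_volumes(0.0, -80.0, 80.0, 0.0)
        report = v.summarize_volumes(mitral, plane_mode="static")
        assert np.isnan(report.regurgitant_volume_direct_ml)
        assert any("static" in n for n in report.notes)

    def test_diastolic_backward_excluded_from_sv(self):
        curve = curve_from_volumes(0.0, 0.0, 80.0, -15.0)
        report = v.summarize_volumes(curve)
        assert report.mitral_sv_ml == pytest.approx(80.0)


class TestDiastolicPeaks:
    def make_series(self, flat_series, early_vel, late_vel):
        series = flat_series.copy()
        series.velocity[2:4] = early_vel  # cm/s
        series.velocity[6:8] = late_vel
        return series

    def test_uniform_early_velocity(self, flat_series):
        series = self.make_series(flat_series, 60.0, 0.0)
        roi = roi_series(square_roi(5, 5, 14, 14))
        e, _, _ = fq.diastolic_peaks(series, roi, (2, 4), (6, 8))
        assert e == pytest.approx(0.6)

    def test_constructed_lobes_ratio(self, flat_series):
        series = self.make_series(flat_series, 60.0, 40.0)
        roi = roi_series(square_roi(5, 5, 14, 14))
        e, a, ratio = fq.diastolic_peaks(series, roi, (2, 4), (6, 8))
        assert (e, a) == (pytest.approx(0.6), pytest.approx(0.4))
        assert ratio == pytest.approx(1.5)

    def test_zero_late_flow_flags_ratio(self, flat_series):
        series = self.make_series(flat_series, 60.0, 0.0)
        roi = roi_series(square_roi(5, 5, 14, 14))
        e, a, ratio = fq.diastolic_peaks(series, roi, (2, 4), (6, 8))
        assert a == pytest.approx(0.0)
        assert np.isnan(ratio)

    def test_percentile_tempers_hot_pixels(self, flat_series):
        series = self.make_series(flat_series, 60.0, 40.0)
        series.velocity[2, 7, 7] = 500.0  # single outlier pixel
        roi = roi_series(square_roi(5, 5, 14, 14))
        e, _, _ = fq.diastolic_peaks(series, roi, (2, 4), (6, 8))
        assert e < 1.0

    def test_phase_maxima_mode(self, flat_series):
        series = self.make_series(flat_series, 60.0, 40.0)
        roi = roi_series(square_roi(5, 5, 14, 14))
        e, a, _ = fq.diastolic_peaks(series, roi, (2, 4), (6, 8), mode="phase_maxima")
        assert e == pytest.approx(0.6)

    def test_overlapping_windows_rejected(self, flat_series):
        roi = roi_series(square_roi(5, 5, 14, 14))
        with pytest.raises(ValueError, match="disjoint"):
            fq.diastolic_peaks(flat_series, roi, (2, 6), (5, 8))


class TestPlanimetricVolumes:
    def test_single_slice(self):
        stack = fq.ShortAxisStack(np.array([[10.0, 5.0]]), 10.0, 0, 1)
        edv, esv, sv = fq.planimetric_volumes(stack)
        assert (edv, esv, sv) == (pytest.approx(10.0), pytest.approx(5.0), pytest.approx(5.0))

    def test_three_slice_hand_sum(self):
        areas = np.array([[12.0, 8.0], [10.0, 6.0], [5.0, 2.0]])
        stack = fq.ShortAxisStack(areas, 8.0, 0, 1)
        edv, esv, sv = fq.planimetric_volumes(stack)
        assert edv == pytest.approx(27.0 * 0.8)
        assert esv == pytest.approx(16.0 * 0.8)
        assert sv == pytest.approx(11.0 * 0.8)

    def test_equal_phases_zero_sv(self):
        stack = fq.ShortAxisStack(np.array([[7.0, 7.0]]), 10.0, 0, 1)
        assert fq.planimetric_volumes(stack)[2] == pytest.approx(0.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fq.ShortAxisStack(np.array([[-1.0, 0.0]]), 10.0, 0, 1)
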