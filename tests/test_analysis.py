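import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopierce.analysis import (
    AnalysisConfig,
    detect_contact_point,
    detect_force_drops,
    fit_hertz,
    hertz_force,
    indentation_depth,
    segment_curve,
)
from nanopierce.core import ForceCurve, NoContactError, SegmentationError
from nanopierce.synth import CurveGenParams, generate_condition_set, generate_curve


class TestIndentationDepth:
    def test_hand_arithmetic(self):
        # 1000 nm past contact at 2 nN with k = 0.02 N/m: deflection 100 nm
        depth = indentation_depth(np.array([1000.0]), np.array([2.0]), 0.02, 0.0)
        assert depth[0] == pytest.approx(900.0)

    def test_rigid_cantilever_limit(self):
        z = np.linspace(0, 500, 50)
        f = np.linspace(0, 10, 50)
        depth = indentation_depth(z, f, 1e6, 0.0)
        np.testing.assert_allclose(depth, z, atol=1e-4)

    def test_zero_force_gives_piezo_travel(self):
        z = np.linspace(0, 500, 50)
        depth = indentation_depth(z, np.zeros(50), 0.02, 0.0)
        np.testing.assert_allclose(depth, z)

    def test_floored_at_zero(self):
        depth = indentation_depth(np.array([10.0]), np.array([5.0]), 0.02, 0.0)
        assert depth[0] == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            indentation_depth(np.array([1.0]), np.array([1.0]), -0.02, 0.0)
        with pytest.raises(ValueError):
            indentation_depth(np.array([]), np.array([]), 0.02, 0.0)


class TestHertzForce:
    def test_zero_depth(self):
        assert hertz_force(1000.0, 2.25, 0.5, 0.0) == 0.0

    def test_direct_evaluation(self):
        # (4/3) sqrt(2.25e-6) * 1000 / 0.75 * (5e-7)^1.5 = 9.4281e-10 N
        assert hertz_force(1000.0, 2.25, 0.5, 500.0) == pytest.approx(0.94281, rel=1e-4)

    def test_linearity_in_modulus(self):
        f1 = hertz_force(1000.0, 2.25, 0.5, 300.0)
        f2 = hertz_force(2000.0, 2.25, 0.5, 300.0)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_invalid_poisson(self):
        with pytest.raises(ValueError):
            hertz_force(1000.0, 2.25, 1.0, 100.0)

    @given(e=st.floats(10.0, 1e5), d=st.floats(0.0, 2000.0))
    @settings(max_examples=50, deadline=None)
    def test_non_negative_and_monotone(self, e, d):
        f = hertz_force(e, 2.25, 0.5, d)
        assert f >= 0.0
        assert hertz_force(e, 2.25, 0.5, d + 1.0) >= f


class TestContactDetection:
    def test_noiseless_exact(self):
        curve = generate_curve(CurveGenParams(noise_sd=0.0, seed=1))
        z_a = detect_contact_point(curve)
        assert abs(z_a - curve.ground_truth.contact_z) <= curve.piezo_z[1] - curve.piezo_z[0]

    def test_noisy_within_20nm(self):
        for seed in range(10):
            curve = generate_curve(CurveGenParams(noise_sd=0.01, seed=seed))
            z_a = detect_contact_point(curve)
            assert abs(z_a - curve.ground_truth.contact_z) <= 20.0

    def test_all_zero_trace_raises(self):
        curve = ForceCurve(
            piezo_z=np.arange(0.0, 1000.0, 2.0),
            force=np.zeros(500),
            spring_constant=0.02,
            approach_speed=1.0,
            trigger_force=12.0,
            tip_kind="pyramid",
            tip_radius=0.01,
        )
        with pytest.raises(NoContactError):
            detect_contact_point(curve)


class TestHertzFit:
    def test_noiseless_oracle_equivalence(self, sphere_params):
        curve = generate_curve(sphere_params)
        fit = fit_hertz(curve)
        assert fit.modulus == pytest.approx(sphere_params.cell_modulus, rel=1e-3)
        assert fit.contact_point == pytest.approx(1000.0, abs=2.0)
        assert fit.rms_residual < 1e-6

    @pytest.mark.parametrize("modulus", [423.0, 1862.0])
    def test_noiseless_reported_moduli(self, sphere_params, modulus):
        params = dataclasses.replace(sphere_params, cell_modulus=modulus)
        fit = fit_hertz(generate_curve(params))
        assert fit.modulus == pytest.approx(modulus, rel=0.01)

    def test_noisy_mean_recovery(self, sphere_params):
        params = dataclasses.replace(sphere_params, noise_sd=0.05)
        moduli = []
        for seed in range(30):
            curve = generate_curve(dataclasses.replace(params, seed=seed))
            moduli.append(fit_hertz(curve).modulus)
        assert np.mean(moduli) == pytest.approx(1000.0, rel=0.05)

    def test_pyramid_rejected(self, pyramid_params):
        curve = generate_curve(pyramid_params)
        with pytest.raises(ValueError):
            fit_hertz(curve)


class TestDropDetection:
    def test_drop_free_curve_empty(self):
        curve = generate_curve(CurveGenParams(penetration_probability=0.0, seed=3))
        assert detect_force_drops(curve) == []

    def test_single_planted_drop_recovered(self):
        params = CurveGenParams(penetration_probability=1.0, noise_sd=0.02, seed=4)
        curve = generate_curve(params)
        events = detect_force_drops(curve)
        truth = curve.ground_truth.events
        assert len(events) == len(truth) == 1
        assert events[0].insertion_force == pytest.approx(truth[0].force, abs=3 * 0.02)
        assert abs(events[0].index - truth[0].index) <= 2

    def test_two_drops_ranked(self):
        params = CurveGenParams(penetration_probability=1.0, second_drop_probability=1.0,
                                noise_sd=0.02, seed=5)
        found = 0
        for curve in generate_condition_set(params, 10):
            events = detect_force_drops(curve)
            truth = curve.ground_truth.events
            if len(truth) == 2:
                found += 1
                assert len(events) == 2
                assert events[0].rank == "membrane_first"
                assert events[1].rank == "nucleus_second"
                assert events[0].index < events[1].index
        assert found >= 5

    def test_time_displacement_consistency(self):
        params = CurveGenParams(penetration_probability=1.0, seed=6, approach_speed=2.0)
        curve = generate_curve(params)
        for ev in detect_force_drops(curve):
            assert ev.insertion_time * curve.approach_speed == pytest.approx(
                ev.insertion_displacement, rel=1e-12
            )

    def test_noiseless_indices_exact(self):
        params = CurveGenParams(penetration_probability=1.0, noise_sd=0.0, seed=7)
        for curve in generate_condition_set(params, 10):
            events = detect_force_drops(curve)
            truth = curve.ground_truth.events
            assert len(events) == len(truth)
            for ev, tr in zip(events, truth):
                assert abs(ev.index - tr.index) <= 2


class TestSegmentation:
    def test_noiseless_slope_exact(self):
        params = CurveGenParams(membrane_slope=3.0, penetration_probability=1.0,
                                noise_sd=0.0, seed=8)
        curve = generate_curve(params)
        events = detect_force_drops(curve)
        seg = segment_curve(curve, events)
        assert seg.ab_slope == pytest.approx(3.0, abs=1e-6)
        assert seg.ab_slope_r2 == pytest.approx(1.0, abs=1e-9)
        assert seg.contact_index < seg.first_drop_index < seg.trigger_index

    def test_condition_slope_ordering(self):
        means = []
        for slope in (2.0, 6.0):
            params = CurveGenParams(membrane_slope=slope, penetration_probability=1.0,
                                    noise_sd=0.02, seed=9)
            slopes = []
            for curve in generate_condition_set(params, 15):
                events = detect_force_drops(curve)
                slopes.append(segment_curve(curve, events).ab_slope)
            means.append(np.mean(slopes))
        assert means[1] > means[0]

    def test_no_event_fits_to_trigger(self):
        curve = generate_curve(CurveGenParams(penetration_probability=0.0, seed=10))
        seg = segment_curve(curve, [])
        assert seg.first_drop_index is None
        assert seg.ab_slope > 0

    def test_degenerate_segment_raises(self):
        params = CurveGenParams(penetration_probability=1.0, noise_sd=0.0, seed=11)
        curve = generate_curve(params)
        events = detect_force_drops(curve)
        events[0] = dataclasses.replace(events[0], index=curve.ground_truth.contact_index + 2)
        with pytest.raises(SegmentationError):
            segment_curve(curve, events)


def test_false_positive_rate_moderate_batch():
    """Spot check of the detector false-positive budget (full run in acceptance)."""
    params = CurveGenParams(penetration_probability=0.0, noise_sd=0.05, seed=12)
    curves = generate_condition_set(params, 100)
    fp = sum(1 for c in curves if detect_force_drops(c))
    assert fp <= 1


def test_custom_config_threshold_respected():
    cfg = AnalysisConfig(drop_floor_nn=5.0, drop_sd_mult=50.0)
    params = CurveGenParams(penetration_probability=1.0, noise_sd=0.02, seed=13)
    curve = generate_curve(params)
    assert detect_force_drops(curve, config=cfg) == []
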