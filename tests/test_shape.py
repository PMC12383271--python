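"""Eccentricity metrics, segmentation and transition-fit recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import regionprops

import phenotrack as pt
from phenotrack.presets import ShapeTransitionModel, ValidationError
from phenotrack.shape import eccentricity_from_axes


def _ellipse_mask(a, b, angle=0.0, size=201):
    """Filled ellipse with semi-axes a >= b rotated by ``angle``."""
    c = size // 2
    gy, gx = np.mgrid[0:size, 0:size]
    dx, dy = gx - c, gy - c
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestMeasureEccentricity:
    def test_circle_is_spherical(self):
        fit = pt.measure_eccentricity(_ellipse_mask(40, 40))
        assert fit.eccentricity < 0.02

    def test_three_to_one_ellipse_analytic_metrics(self):
        mask = _ellipse_mask(60, 20)
        moment = pt.measure_eccentricity(mask, metric="moment")
        elong = pt.measure_eccentricity(mask, metric="elongation")
        assert moment.eccentricity == pytest.approx(np.sqrt(1 - 1 / 9), abs=0.01)
        assert elong.eccentricity == pytest.approx(1 - 1 / 3, abs=0.01)

    def test_rotation_invariance(self):
        base = pt.measure_eccentricity(_ellipse_mask(120, 40, 0.0, size=401))
        rot = pt.measure_eccentricity(_ellipse_mask(120, 40, np.deg2rad(37), size=401))
        assert abs(base.eccentricity - rot.eccentricity) < 1e-3

    def test_agrees_with_regionprops(self):
        mask = _ellipse_mask(50, 25, angle=0.7)
        fit = pt.measure_eccentricity(mask, metric="moment")
        props = regionprops(mask.astype(int))[0]
        assert fit.eccentricity == pytest.approx(props.eccentricity, abs=1e-6)
        assert fit.major == pytest.approx(props.axis_major_length, rel=1e-6)

    def test_degenerate_region_flagged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 3:12] = True  # collinear pixels
        fit = pt.measure_eccentricity(mask)
        assert fit.degenerate and fit.eccentricity == 1.0

    def test_small_region_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValidationError):
            pt.measure_eccentricity(mask)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(a=st.floats(1.0, 100.0), b=st.floats(1.0, 100.0))
def test_metric_ordering_property(a, b):
    """moment metric >= elongation metric >= 0, equality iff a == b."""
    a, b = max(a, b), min(a, b)
    moment = eccentricity_from_axes(a, b, "moment")
    elong = eccentricity_from_axes(a, b, "elongation")
    axis = eccentricity_from_axes(a, b, "axisratio")
    assert moment >= elong >= axis >= 0
    if a == b:
        assert moment == elong == 0


class TestSegmentCell:
    def test_isolated_blob_mask_brackets_footprint(self):
        sigma = 4.0
        gy, gx = np.mgrid[0:101, 0:101]
        frame = 600.0 * np.exp(-((gx - 50) ** 2 + (gy - 50) ** 2) / (2 * sigma**2))
        mask = pt.segment_cell(frame, 50, 50)
        # Otsu on a sparse window thresholds below half maximum; the mask is
        # a superlevel set bracketed by the half-max footprint and ~2.2x it
        half_max_area = np.pi * 2 * np.log(2) * sigma**2
        assert half_max_area <= mask.sum() <= 2.2 * half_max_area
        assert mask[50, 50]

    def test_blank_window_skipped(self):
        assert pt.segment_cell(np.zeros((64, 64)), 32, 32) is None

    def test_touching_blobs_resolved_to_own_component(self):
        gy, gx = np.mgrid[0:101, 0:161]
        frame = 500.0 * np.exp(-((gx - 50) ** 2 + (gy - 50) ** 2) / 18.0)
        frame += 500.0 * np.exp(-((gx - 110) ** 2 + (gy - 50) ** 2) / 18.0)
        mask = pt.segment_cell(frame, 50, 50, window=201)
        assert mask[50, 50] and not mask[50, 110]

    def test_detection_outside_frame_rejected(self):
        with pytest.raises(ValidationError):
            pt.segment_cell(np.zeros((10, 10)), 50, 50)


class TestFitShapeTransition:
    def test_noiseless_self_consistency(self):
        model = ShapeTransitionModel(0.1, 0.9, 15.0, 0.0)
        s = pt.simulate_shape_series(model, 45.0, 0.5, seed=0)
        fit = pt.fit_shape_transition(s["time_min"], s["eccentricity"])
        assert fit.converged
        assert fit.tau_shape == pytest.approx(15.0, rel=1e-3)
        assert fit.epsilon_start == pytest.approx(0.1, abs=1e-6)
        assert fit.epsilon_final == pytest.approx(0.9, abs=1e-6)

    def test_constant_series_not_converged(self):
        t = np.linspace(0, 45, 60)
        fit = pt.fit_shape_transition(t, np.full(60, 0.4))
        assert not fit.converged and np.isnan(fit.tau_shape)

    def test_monte_carlo_recovery_noisy(self):
        model = ShapeTransitionModel(0.1, 0.94, 15.0, 0.05)
        taus = []
        for seed in range(60):
            s = pt.simulate_shape_series(model, 45.0, 0.5, seed=seed)
            fit = pt.fit_shape_transition(s["time_min"], s["eccentricity"])
            if fit.converged:
                taus.append(fit.tau_shape)
        assert np.median(taus) == pytest.approx(15.0, rel=0.15)

    @pytest.mark.parametrize("tau", [5.0, 15.0, 30.0])
    def test_recovery_across_timescales(self, tau):
        model = ShapeTransitionModel(0.1, 0.94, tau, 0.05)
        errs = []
        for seed in range(40):
            s = pt.simulate_shape_series(model, max(45.0, 3 * tau), 0.5, seed=seed)
            fit = pt.fit_shape_transition(s["time_min"], s["eccentricity"])
            if fit.converged:
                errs.append(abs(fit.tau_shape - tau) / tau)
        assert np.median(errs) < 0.15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            pt.fit_shape_transition(np.arange(5.0), np.arange(5.0) / 10)


class TestDeltaEccentricity:
    def test_identical_groups_zero(self):
        out = pt.delta_eccentricity([0.3, 0.4], [0.4, 0.3])
        assert out["delta_ecc"] == 0.0

    def test_forced_arithmetic(self):
        out = pt.delta_eccentricity(np.full(5, 0.7), np.full(8, 0.1))
        assert out["delta_ecc"] == pytest.approx(0.6)

    def test_replicate_means_match_brute_force(self):
        rng = np.random.default_rng(0)
        treat = rng.uniform(0.4, 0.9, 30)
        ctrl = rng.uniform(0.0, 0.3, 30)
        reps = np.repeat(["a", "b", "c"], 10)
        out = pt.delta_eccentricity(treat, ctrl, reps, reps)
        for rep in "abc":
            sel = reps == rep
            expected = abs(treat[sel].mean() - ctrl[sel].mean())
            assert out["replicate_deltas"][rep] == pytest.approx(expected, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            pt.delta_eccentricity([], [0.1])


@pytest.mark.parametrize("ecc_true", [0.0, 0.3, 0.6, 0.8, 0.95])
def test_rendered_cell_roundtrip_across_eccentricities(ecc_true):
    """Rendering a cell with a known eccentricity, segmenting it and
    re-measuring (intensity-weighted) recovers the value within 0.05 on
    noiseless frames."""
    import pandas as pd

    scene = pt.SceneConfig(width=101, height=101, n_frames=1, noise_sd=0.0,
                           background_level=0.0)
    gt = pd.DataFrame(
        {
            "cell_id": [0],
            "frame": [0],
            "x_px": [50.3],
            "y_px": [50.6],
            "heading_rad": [0.7],
            "eccentricity": [ecc_true],
            "body_length_um": [6.0],
        }
    )
    frame = pt.render_video(gt, scene)[0].astype(float)
    mask = pt.segment_cell(frame, 50.3, 50.6)
    fit = pt.measure_cell(frame, mask)
    assert abs(fit.eccentricity - ecc_true) < 0.05
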