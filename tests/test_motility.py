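"""Speed, heading and persistence estimators against closed forms and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenotrack as pt
from phenotrack.motility import directional_correlation, speed_summary
from phenotrack.presets import ValidationError

from _reference import ref_savgol, ref_unwrap


class TestSmoothPositions:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(30, dtype=float)
        x = 3.0 + 0.5 * t - 0.02 * t**2
        y = -1.0 + 0.1 * t + 0.03 * t**2
        sx, sy = pt.smooth_positions(x, y)
        assert np.allclose(sx, x, atol=1e-10)
        assert np.allclose(sy, y, atol=1e-10)

    def test_constant_positions_unchanged(self):
        x = np.full(10, 7.0)
        sx, _ = pt.smooth_positions(x, x)
        assert np.allclose(sx, 7.0, atol=1e-12)

    def test_matches_sliding_polyfit_oracle(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 40) + rng.normal(0, 0.3, 40)
        sx, _ = pt.smooth_positions(x, x)
        assert np.max(np.abs(sx - ref_savgol(x))) < 1e-9

    def test_short_track_rejected(self):
        with pytest.raises(ValidationError):
            pt.smooth_positions(np.arange(4.0), np.arange(4.0))


class TestComputeVelocity:
    def test_forced_arithmetic_straight_line(self):
        frames = np.arange(20)
        x = 10.0 * frames
        speeds = pt.compute_velocity(frames, x, np.zeros(20), fps=25, pixel_size=0.65)
        assert np.allclose(speeds, 162.5, atol=1e-9)
        assert speeds.size == 20 - 1 - 4  # ends truncated by the 5-frame boxcar

    def test_stationary_track_zero(self):
        frames = np.arange(10)
        speeds = pt.compute_velocity(frames, np.zeros(10), np.zeros(10), 25, 0.65)
        assert np.all(speeds == 0)

    def test_gap_uses_true_elapsed_time(self):
        frames = np.array([0, 1, 2, 3, 6, 7, 8, 9])  # 3-frame gap, same velocity
        x = 2.0 * frames
        speeds = pt.compute_velocity(frames, x, np.zeros_like(x), 25, 1.0)
        assert np.allclose(speeds, 2.0 * 25)

    def test_unit_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        frames = np.arange(30)
        x = np.cumsum(rng.normal(0, 2, 30))
        y = np.cumsum(rng.normal(0, 2, 30))
        a = pt.compute_velocity(frames, x, y, fps=25, pixel_size=0.65)
        b = pt.compute_velocity(frames, x, y, fps=50, pixel_size=0.325)
        assert np.allclose(a, b, rtol=1e-12)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValidationError):
            pt.compute_velocity(np.arange(10), np.arange(10.0), np.zeros(10), 0, 0.65)


class TestHeadingSeries:
    def test_motion_along_x_gives_zero(self):
        theta, carried = pt.heading_series(np.arange(10.0), np.zeros(10))
        assert np.allclose(theta, 0.0)
        assert not carried.any()

    def test_quarter_circle_spans_half_pi(self):
        phi = np.linspace(0, np.pi / 2, 200)
        theta, _ = pt.heading_series(np.cos(phi), np.sin(phi))
        assert np.all(np.diff(theta) > 0) or np.all(np.diff(theta) < 0)
        assert abs(abs(theta[-1] - theta[0]) - np.pi / 2) < 0.02

    def test_zero_step_carries_heading_forward(self):
        x = np.array([0.0, 1.0, 1.0, 2.0])
        theta, carried = pt.heading_series(x, np.zeros(4))
        assert carried.tolist() == [False, True, False]
        assert theta[1] == theta[0]

    def test_unwrap_matches_minimal_jump_oracle(self):
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 0.8, 300)
        x = np.cumsum(np.cos(np.cumsum(steps)))
        y = np.cumsum(np.sin(np.cumsum(steps)))
        theta, _ = pt.heading_series(x, y)
        raw = np.arctan2(np.diff(y), np.diff(x))
        assert np.allclose(theta, ref_unwrap(raw), atol=1e-9)
        assert np.max(np.abs(np.diff(theta))) <= np.pi


class TestPersistenceTime:
    def test_directional_correlation_starts_at_one(self):
        rng = np.random.default_rng(0)
        theta = np.cumsum(rng.normal(0, 0.2, 100))
        corr = directional_correlation(theta, 30)
        assert corr[0] == 1.0

    def test_straight_track_flagged_infinite(self):
        fit = pt.persistence_time(np.zeros(100), dt=0.04)
        assert np.isinf(fit.tau) and not fit.converged

    @pytest.mark.parametrize("tau_true", [2.8, 7.2])
    def test_ensemble_recovery_within_15_percent(self, tau_true):
        preset = pt.MotilityPreset(
            "t", 20.0, 0.0, tau_true, 0.1, 4.5, 4.4
        )
        tracks = pt.simulate_ensemble(preset, 300, 30.0, 0.04, seed=int(tau_true * 100))
        taus = []
        for tr in tracks:
            sx, sy = pt.smooth_positions(tr.x, tr.y)
            theta, _ = pt.heading_series(sx, sy)
            fit = pt.persistence_time(theta, 0.04)
            if fit.converged and np.isfinite(fit.tau):
                taus.append(fit.tau)
        assert np.median(taus) == pytest.approx(tau_true, rel=0.15)

    def test_recovered_ratio_matches_phase_contrast(self):
        # amoeboid cells change direction roughly three times less often
        hap = pt.simulate_ensemble(pt.HAPLOID_PRESET, 150, 30.0, 0.04, seed=5)
        amb = pt.simulate_ensemble(pt.AMOEBOID_PRESET, 150, 30.0, 0.04, seed=6)

        def median_tau(tracks):
            taus = []
            for tr in tracks:
                theta, _ = pt.heading_series(*pt.smooth_positions(tr.x, tr.y))
                fit = pt.persistence_time(theta, 0.04)
                if fit.converged and np.isfinite(fit.tau):
                    taus.append(fit.tau)
            return np.median(taus)

        ratio = median_tau(amb) / median_tau(hap)
        assert ratio == pytest.approx(7.2 / 2.8, rel=0.25)

    def test_raw_angle_mode_runs(self):
        rng = np.random.default_rng(8)
        theta = np.cumsum(rng.normal(0, 0.17, 751))
        fit = pt.persistence_time(theta, 0.04, mode="raw_angle")
        assert fit.mode == "raw_angle"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            pt.persistence_time(np.zeros(10), dt=0.04)


class TestSpeedSummary:
    @staticmethod
    def _summary_frame(speeds, reps):
        return pd.DataFrame(
            {
                "track_id": np.arange(len(speeds)),
                "replicate": reps,
                "n_frames": 100,
                "mean_speed_um_s": speeds,
                "speed_sd": 0.0,
                "tau_c_s": 1.0,
                "fit_ok": True,
            }
        )

    def test_single_track_single_replicate(self):
        out = speed_summary(self._summary_frame([10.0], ["a"]))
        assert out["mean_speed_um_s"] == 10.0
        assert np.isnan(out["speed_sem"])  # SEM undefined with one replicate

    def test_sem_across_replicates_not_tracks(self):
        speeds = [10.0, 10.0, 20.0, 20.0]
        out = speed_summary(self._summary_frame(speeds, ["a", "a", "b", "b"]))
        assert out["mean_speed_um_s"] == 15.0
        # two replicate means 10 and 20 -> SEM = 5/sqrt(2)*sqrt(2) = 5
        assert out["speed_sem"] == pytest.approx(np.std([10, 20], ddof=1) / np.sqrt(2))

    def test_pdf_normalized(self):
        rng = np.random.default_rng(0)
        out = speed_summary(self._summary_frame(rng.uniform(5, 30, 200), ["a"] * 200))
        density, edges = out["speed_pdf"]
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_generative_recovery_within_2_sem(self):
        tracks = pt.simulate_ensemble(pt.HAPLOID_PRESET, 240, 2.0, 0.1, seed=10)
        speeds = np.array([tr.speed for tr in tracks])
        reps = np.repeat([f"r{i}" for i in range(8)], 30)
        out = speed_summary(self._summary_frame(speeds, reps))
        sem = max(out["speed_sem"], 1e-6)
        assert abs(out["mean_speed_um_s"] - 26.3) < 2 * sem + 0.5


@settings(derandomize=True, deadline=None, max_examples=30)
@given(
    fps=st.floats(5.0, 100.0),
    scale=st.floats(0.1, 5.0),
)
def test_speed_scale_consistency_property(fps, scale):
    """Speed in µm/s is invariant under consistent pixel/frame rescaling."""
    frames = np.arange(12)
    x = np.cumsum(np.linspace(1.0, 2.0, 12))
    y = np.cumsum(np.linspace(0.5, 1.0, 12))
    base = pt.compute_velocity(frames, x, y, fps=fps, pixel_size=0.65)
    rescaled = pt.compute_velocity(
        frames, x * scale, y * scale, fps=fps, pixel_size=0.65 / scale
    )
    assert np.allclose(base, rescaled, rtol=1e-9)
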