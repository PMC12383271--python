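"""Render ground-truth cells into synthetic microscopy video.

Cells are drawn as anisotropic Gaussian intensity blobs — bright on a dark
background, equivalent to the magnitude images produced by temporal-median
background subtraction of phase-contrast video.  The blob's axis ratio is set
by the cell's instantaneous moment eccentricity and its long axis is aligned
with the swimming heading, so segmenting a rendered cell and re-measuring its
moment eccentricity recovers the ground-truth value.

Cells that swim out of the field of view are simply truncated (they stop
being rendered), as in real imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .presets import MotilityPreset, ValidationError
from .simulate import simulate_trajectory

__all__ = ["SceneConfig", "render_video", "simulate_scene"]


@dataclass
class SceneConfig:
    """Imaging geometry and camera model for a rendered scene.

    ``duration`` is in seconds; the frame count is ``round(duration * fps)``
    unless ``n_frames`` is given explicitly, in which case the frame count is
    authoritative and the effective duration is ``n_frames / fps``.
    ``pixel_size`` defaults to 0.65 µm/px (10x objective, 6.5 µm camera
    pixels).
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.65
    fps: float = 25.0
    duration: float = 24.0
    n_frames: int | None = None
    n_cells: int = 5
    background_level: float = 100.0
    background_gradient: float = 0.0
    noise_sd: float = 0.0
    cell_intensity: float = 800.0
    dtype: str = "uint16"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration <= 0 or self.pixel_size <= 0:
            raise ValidationError("fps, duration and pixel_size must be > 0")
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("frame dimensions must be > 0")
        if self.dtype not in ("uint8", "uint16"):
            raise ValidationError("dtype must be 'uint8' or 'uint16'")

    @property
    def frame_count(self) -> int:
        if self.n_frames is not None:
            return int(self.n_frames)
        return int(round(self.duration * self.fps))

    @property
    def effective_duration(self) -> float:
        return self.frame_count / self.fps

    def background(self) -> np.ndarray:
        """Static background image: constant level plus a horizontal ramp."""
        cols = np.arange(self.width, dtype=np.float64)
        return np.broadcast_to(
            self.background_level + self.background_gradient * cols,
            (self.height, self.width),
        ).astype(np.float64)


def _blob_sigmas(ecc: float, body_length_px: float) -> tuple[float, float]:
    """Gaussian sigmas (along, across) for a blob of given moment
    eccentricity whose FWHM along the long axis matches the body length."""
    sigma_a = max(body_length_px / 2.355, 0.8)
    sigma_b = sigma_a * np.sqrt(max(1.0 - ecc * ecc, 1e-6))
    return sigma_a, sigma_b


def render_video(ground_truth: pd.DataFrame, scene: SceneConfig) -> np.ndarray:
    """Rasterize a ground-truth table into an image stack.

    ``ground_truth`` must carry one row per cell per frame with columns
    ``cell_id, frame, x_px, y_px, heading_rad, eccentricity, body_length_um``
    (see :func:`simulate_scene`).  Returns an array of shape
    ``(frames, height, width)`` in the configured dtype; output is
    byte-identical for a fixed scene seed.
    """
    n_frames = scene.frame_count
    if len(ground_truth) and int(ground_truth["frame"].max()) >= n_frames:
        raise ValidationError("ground truth extends past the scene frame count")
    bg = scene.background()
    info = np.iinfo(np.dtype(scene.dtype))
    stack = np.empty((n_frames, scene.height, scene.width), dtype=scene.dtype)
    rng = (
        np.random.default_rng(np.random.SeedSequence([scene.seed, 0xBEEF]))
        if scene.noise_sd > 0
        else None
    )
    by_frame = (
        dict(tuple(ground_truth.groupby("frame"))) if len(ground_truth) else {}
    )
    # rendered one frame at a time to bound memory on long clips
    for f in range(n_frames):
        img = bg.copy()
        rows = by_frame.get(f)
        if rows is not None:
            for row in rows.itertuples(index=False):
                cx, cy = float(row.x_px), float(row.y_px)
                ecc = float(row.eccentricity)
                length_px = float(row.body_length_um) / scene.pixel_size
                sig_a, sig_b = _blob_sigmas(ecc, length_px)
                r = int(np.ceil(4.0 * sig_a))
                if 2 * r + 1 > min(scene.height, scene.width):
                    raise ValidationError("cell footprint larger than the frame")
                x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
                y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
                xs0, xs1 = max(x0, 0), min(x1, scene.width)
                ys0, ys1 = max(y0, 0), min(y1, scene.height)
                if xs0 >= xs1 or ys0 >= ys1:
                    continue  # fully out of view
                dx, dy = np.meshgrid(np.arange(xs0, xs1) - cx, np.arange(ys0, ys1) - cy)
                th = float(row.heading_rad)
                u = dx * np.cos(th) + dy * np.sin(th)   # along the body axis
                v = -dx * np.sin(th) + dy * np.cos(th)  # across
                img[ys0:ys1, xs0:xs1] += scene.cell_intensity * np.exp(
                    -0.5 * ((u / sig_a) ** 2 + (v / sig_b) ** 2)
                )
        if rng is not None:
            img += rng.normal(0.0, scene.noise_sd, size=img.shape)
        stack[f] = np.clip(np.rint(img), info.min, info.max).astype(scene.dtype)
    return stack


def _place_cells(
    n: int, scene: SceneConfig, min_spacing_px: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Rejection-sample initial positions (px) at least ``min_spacing_px``
    apart, inside a central margin that leaves room to swim."""
    margin = min(scene.width, scene.height) * 0.15
    placed: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(placed) == n:
            break
        p = (
            rng.uniform(margin, scene.width - margin),
            rng.uniform(margin, scene.height - margin),
        )
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_spacing_px for q in placed):
            placed.append(p)
    if len(placed) < n:
        raise ValidationError(
            f"could not place {n} cells {min_spacing_px} px apart in the frame"
        )
    return placed


def simulate_scene(
    presets: Sequence[MotilityPreset],
    scene: SceneConfig,
    min_spacing_px: float = 120.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one cell per entry of ``presets`` and render the scene.

    Returns ``(ground_truth, stack)`` where the ground-truth table has one
    row per cell per frame with pixel and micron positions, heading, true
    speed, eccentricity and the phenotype label.
    """
    rng_place = np.random.default_rng(np.random.SeedSequence([scene.seed, 0xACE]))
    starts = _place_cells(len(presets), scene, min_spacing_px, rng_place)
    dt = 1.0 / scene.fps
    duration = (scene.frame_count - 1) * dt
    children = np.random.SeedSequence(scene.seed).spawn(len(presets))

    frames = []
    for cell_id, (preset, (sx, sy), child) in enumerate(zip(presets, starts, children)):
        traj = simulate_trajectory(
            preset,
            duration,
            dt,
            seed=np.random.default_rng(child),
            origin=(sx * scene.pixel_size, sy * scene.pixel_size),
        )
        df = pd.DataFrame(
            {
                "cell_id": cell_id,
                "frame": np.arange(len(traj)),
                "x_px": traj.x / scene.pixel_size,
                "y_px": traj.y / scene.pixel_size,
                "x_um": traj.x,
                "y_um": traj.y,
                "heading_rad": traj.heading,
                "speed_um_s": traj.speed,
                "eccentricity": preset.eccentricity_baseline,
                "body_length_um": preset.body_length,
                "phenotype": preset.name,
            }
        )
        if preset.wobble_amplitude > 0:
            phase = 2 * np.pi * traj.t / preset.wobble_period_s
            df["eccentricity"] = np.clip(
                preset.eccentricity_baseline
                + preset.wobble_amplitude * np.sin(phase),
                0.0,
                0.999,
            )
        frames.append(df)
    gt = pd.concat(frames, ignore_index=True)
    stack = render_video(gt, scene)
    return gt, stack
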