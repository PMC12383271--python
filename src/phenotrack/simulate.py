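"""Ground-truthed synthetic data: swimming trajectories, eccentricity time
series and population count tables.

The motility model is two-dimensional rotational diffusion with constant
per-cell speed: the heading angle performs a Brownian walk with increments
``dtheta = sqrt(2*dt/tau_c) * xi`` (``xi`` standard normal), which yields a
single-exponential directional correlation ``<cos dtheta(lag)> =
exp(-lag/tau_c)`` — the simplest generative model whose correlation matches a
single-exponential fit.  Per-cell speeds are drawn once from a normal
truncated at zero.

Randomness uses one root seed; per-cell child streams are spawned with
``numpy.random.SeedSequence`` in cell order, so any single cell can be
re-simulated independently of ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .presets import (
    MotilityPreset,
    ResolutionError,
    ShapeTransitionModel,
    ValidationError,
)

__all__ = [
    "TrajectoryTruth",
    "simulate_trajectory",
    "simulate_ensemble",
    "simulate_shape_series",
    "generate_population_counts",
]


@dataclass
class TrajectoryTruth:
    """Ground truth for one simulated cell: positions in µm, headings in
    radians, a single true speed in µm/s, and the phenotype label."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: float
    phenotype: str

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self, cell_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "frame": np.arange(self.t.size),
                "time_s": self.t,
                "x_um": self.x,
                "y_um": self.y,
                "heading_rad": self.heading,
                "speed_um_s": self.speed,
                "phenotype": self.phenotype,
            }
        )


def _draw_speed(preset: MotilityPreset, rng: np.random.Generator) -> float:
    if preset.speed_sd == 0:
        return preset.mean_speed
    a = (0.0 - preset.mean_speed) / preset.speed_sd  # truncate at zero
    return float(
        stats.truncnorm.rvs(
            a, np.inf, loc=preset.mean_speed, scale=preset.speed_sd, random_state=rng
        )
    )


def simulate_trajectory(
    preset: MotilityPreset,
    duration: float,
    dt: float,
    seed: int | np.random.Generator | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> TrajectoryTruth:
    """Simulate one rotational-diffusion trajectory.

    Parameters
    ----------
    duration, dt
        Clip length and time step in seconds.  The series has
        ``floor(duration/dt) + 1`` samples.  ``dt`` must resolve the heading
        dynamics: ``dt <= 0.2 * tau_c``.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if duration < dt or dt <= 0:
        raise ValidationError("require duration >= dt > 0")
    tau = preset.persistence_time
    if np.isfinite(tau) and dt > 0.2 * tau:
        raise ResolutionError(
            f"dt={dt} too coarse for tau_c={tau}: require dt <= 0.2*tau_c"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = int(np.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    speed = _draw_speed(preset, rng)

    heading = np.empty(n)
    heading[0] = rng.uniform(-np.pi, np.pi)
    if np.isfinite(tau):
        heading[1:] = heading[0] + np.cumsum(
            np.sqrt(2.0 * dt / tau) * rng.standard_normal(n - 1)
        )
    else:
        heading[1:] = heading[0]

    # Position advances by v*dt along the heading held over each step.
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = origin
    x[1:] = x[0] + np.cumsum(speed * dt * np.cos(heading[:-1]))
    y[1:] = y[0] + np.cumsum(speed * dt * np.sin(heading[:-1]))
    return TrajectoryTruth(t=t, x=x, y=y, heading=heading, speed=speed, phenotype=preset.name)


def simulate_ensemble(
    preset: MotilityPreset,
    n_tracks: int,
    duration: float,
    dt: float,
    seed: int = 0,
    origins: Sequence[tuple[float, float]] | None = None,
) -> list[TrajectoryTruth]:
    """Simulate ``n_tracks`` independent trajectories from per-cell child
    streams of one root seed."""
    if n_tracks < 1:
        raise ValidationError("n_tracks must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_tracks)
    out = []
    for i, child in enumerate(children):
        origin = (0.0, 0.0) if origins is None else tuple(origins[i])
        out.append(
            simulate_trajectory(
                preset, duration, dt, seed=np.random.default_rng(child), origin=origin
            )
        )
    return out


def simulate_shape_series(
    model: ShapeTransitionModel,
    duration: float,
    dt: float,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Eccentricity time series for one metamorphosing cell.

    ``duration`` and ``dt`` are in minutes.  Returns columns ``time_min`` and
    ``eccentricity``; the noiseless mean follows the saturating exponential of
    the model and noisy values are clipped into ``[0, 1)``.
    """
    if not duration >= dt > 0:
        raise ValidationError("require duration >= dt > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(int(np.floor(duration / dt)) + 1) * dt
    eps = model.mean(t)
    if model.noise_sd > 0:
        eps = eps + rng.normal(0.0, model.noise_sd, size=t.size)
    eps = np.clip(eps, 0.0, np.nextafter(1.0, 0.0))
    return pd.DataFrame({"time_min": t, "eccentricity": eps})


def generate_population_counts(
    times_days: Sequence[float],
    haploid_start: float = 1.4e6,
    haploid_decline_rate: float = float(np.log(14.0) / 3.0),
    amoeboid_start: float = 7e2,
    amoeboid_plateau: float = 2.627e4,
    amoeboid_rise_tau: float = 1.0,
    bacteria_start: float = 1e8,
    bacteria_growth_rate: float = 0.0,
    noise_cv: float = 0.0,
    sample: str = "5a1",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Generate a tidy count table (cells/ml) for a bacterially challenged
    culture: exponential haploid decline, saturating amoeboid rise, optional
    exponential bacterial growth and multiplicative log-normal noise.

    Default rates reproduce a 1.4e6 -> 1e5 cells/ml haploid crash over three
    days alongside a 7e2 -> 2.5e4 cells/ml amoeboid rise.
    """
    if haploid_start < 0 or amoeboid_start < 0 or bacteria_start < 0:
        raise ValidationError("initial densities must be >= 0")
    if amoeboid_rise_tau <= 0:
        raise ValidationError("amoeboid_rise_tau must be > 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    t = np.asarray(list(times_days), dtype=float)
    rng = np.random.default_rng(seed)

    values = {
        "haploid": haploid_start * np.exp(-haploid_decline_rate * t),
        "amoeboid": amoeboid_plateau
        - (amoeboid_plateau - amoeboid_start) * np.exp(-t / amoeboid_rise_tau),
        "bacteria": bacteria_start * np.exp(bacteria_growth_rate * t),
    }
    rows = []
    for pop, dens in values.items():
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            dens = dens * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
        for day, n in zip(t, dens):
            rows.append((sample, day, pop, float(n)))
    return pd.DataFrame(rows, columns=["sample", "day", "population", "cells_per_ml"])
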