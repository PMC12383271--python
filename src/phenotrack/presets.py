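"""Motility and shape presets for the two *Gephyrocapsa huxleyi* life phases.

The haploid phase is a fast, loosely persistent biflagellate swimmer with a
near-spherical body; the amoeboid phase is slow, directionally persistent and
elongated to roughly a 3:1 ellipsoid.  The numbers stored here are
population-level statistics (mean swimming speed, population SD of per-cell
mean speeds, directional autocorrelation time) and define the default study
conditions for the synthetic-data generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ResolutionError(ValidationError):
    """The requested time step is too coarse for the model dynamics."""


@dataclass(frozen=True)
class MotilityPreset:
    """Generative parameters for one swimming phenotype.

    Parameters
    ----------
    name
        Phenotype label carried through to ground-truth tables.
    mean_speed, speed_sd
        Mean and SD of per-cell swimming speed in µm/s.  Each simulated cell
        draws a single speed from a normal truncated at zero; speed does not
        fluctuate within a track.
    persistence_time
        Directional autocorrelation time tau_c in seconds.  The heading
        undergoes rotational diffusion with diffusivity 1/tau_c so that the
        ensemble directional correlation decays as exp(-lag/tau_c).
    eccentricity_baseline
        Moment eccentricity of the cell body (0 = perfect sphere).
    body_length, body_width
        Major and minor body axes in µm (full lengths, not radii).
    wobble_amplitude
        Optional peak amplitude of a periodic apparent-eccentricity
        modulation that mimics body rotation ("wriggling"); 0 disables it.
    """

    name: str
    mean_speed: float
    speed_sd: float
    persistence_time: float
    eccentricity_baseline: float
    body_length: float
    body_width: float
    wobble_amplitude: float = 0.0
    wobble_period_s: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValidationError("mean_speed and speed_sd must be >= 0")
        if not self.persistence_time > 0:
            raise ValidationError("persistence_time must be > 0 (may be inf)")
        if not 0 <= self.eccentricity_baseline < 1:
            raise ValidationError("eccentricity_baseline must lie in [0, 1)")
        if not self.body_length >= self.body_width > 0:
            raise ValidationError("require body_length >= body_width > 0")


@dataclass(frozen=True)
class ShapeTransitionModel:
    """Saturating-exponential eccentricity rise for the haploid->amoeboid
    metamorphosis: eps(t) = eps_final - (eps_final - eps_start)*exp(-t/tau),
    with tau_shape in minutes and optional additive Gaussian noise."""

    epsilon_start: float = 0.10
    epsilon_final: float = 0.94
    tau_shape: float = 15.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon_start <= self.epsilon_final < 1:
            raise ValidationError("require 0 <= epsilon_start <= epsilon_final < 1")
        if not self.tau_shape > 0:
            raise ValidationError("tau_shape must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def mean(self, t_min):
        """Noiseless eccentricity at time ``t_min`` (minutes)."""
        import numpy as np

        t = np.asarray(t_min, dtype=float)
        return self.epsilon_final - (self.epsilon_final - self.epsilon_start) * np.exp(
            -t / self.tau_shape
        )


def _ecc_to_axis_ratio(ecc: float) -> float:
    """Minor/major axis ratio of an ellipse with moment eccentricity ``ecc``."""
    return math.sqrt(1.0 - ecc * ecc)


# Haploid phase: 26.3 um/s mean speed, population SD 5.6, tau_c 2.8 s,
# ~4.5 um near-spherical body (baseline moment eccentricity 0.10).
HAPLOID = MotilityPreset(
    name="haploid",
    mean_speed=26.3,
    speed_sd=5.6,
    persistence_time=2.8,
    eccentricity_baseline=0.10,
    body_length=4.5,
    body_width=4.5 * _ecc_to_axis_ratio(0.10),
)

# Amoeboid phase: 7.1 um/s mean speed, population SD 0.3, tau_c 7.2 s,
# 3:1 ellipsoid (moment eccentricity sqrt(1 - 1/9) ~ 0.943) of roughly the
# haploid cell volume.
AMOEBOID = MotilityPreset(
    name="amoeboid",
    mean_speed=7.1,
    speed_sd=0.3,
    persistence_time=7.2,
    eccentricity_baseline=math.sqrt(1.0 - 1.0 / 9.0),
    body_length=9.0,
    body_width=3.0,
)

PRESETS = {"haploid": HAPLOID, "amoeboid": AMOEBOID}
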