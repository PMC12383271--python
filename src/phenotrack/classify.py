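"""Phenotype classification of tracked cells.

A track is called *amoeboid* when its average speed is at most 8 µm/s and
its eccentricity at least 0.2 (both thresholds inclusive, interpreted in the
configured eccentricity metric); tracks slower than the motility floor
(default 2 µm/s, separating swimmers from immotile or drifting cells) are
*non-motile*; everything else is *non-amoeboid motile*.  The headline
statistic is the amoeboid fraction among motile cells, with non-motile
tracks excluded from the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .presets import ValidationError

__all__ = [
    "ClassifierConfig",
    "classify_track",
    "classify_tracks",
    "amoeboid_fraction",
    "normalize_to_control",
    "AMOEBOID",
    "NON_AMOEBOID_MOTILE",
    "NON_MOTILE",
]

log = logging.getLogger(__name__)

AMOEBOID = "amoeboid"
NON_AMOEBOID_MOTILE = "non_amoeboid_motile"
NON_MOTILE = "non_motile"


@dataclass
class ClassifierConfig:
    """Decision thresholds: speed_threshold (µm/s, inclusive upper bound for
    amoeboid), eccentricity_threshold (inclusive lower bound, in the
    configured metric), motility_floor (µm/s, below which a track is called
    non-motile).  ``ecc_statistic`` selects whether the per-track mean or
    maximum eccentricity enters the rule."""

    speed_threshold: float = 8.0
    eccentricity_threshold: float = 0.2
    motility_floor: float = 2.0
    ecc_metric: str = "moment"
    ecc_statistic: str = "mean"

    def __post_init__(self) -> None:
        if min(self.speed_threshold, self.eccentricity_threshold, self.motility_floor) < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.ecc_statistic not in ("mean", "max"):
            raise ValidationError("ecc_statistic must be 'mean' or 'max'")


def classify_track(
    mean_speed: float, mean_ecc: float, config: ClassifierConfig | None = None
) -> str:
    """Classify one track from its average speed (µm/s) and eccentricity."""
    config = config or ClassifierConfig()
    if not (np.isfinite(mean_speed) and np.isfinite(mean_ecc)):
        raise ValidationError("features must be finite")
    if mean_speed < 0 or mean_ecc < 0:
        raise ValidationError("features must be >= 0")
    if mean_speed < config.motility_floor:
        return NON_MOTILE
    if mean_speed <= config.speed_threshold and mean_ecc >= config.eccentricity_threshold:
        return AMOEBOID
    return NON_AMOEBOID_MOTILE


def classify_tracks(
    summary: pd.DataFrame, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Classify every row of a per-track summary.

    Requires columns ``track_id, mean_speed_um_s, mean_ecc`` (plus optional
    ``replicate``); returns the table with a ``label`` column appended.
    """
    config = config or ClassifierConfig()
    out = summary.copy()
    out["label"] = [
        classify_track(s, e, config)
        for s, e in zip(out["mean_speed_um_s"], out["mean_ecc"])
    ]
    return out


def amoeboid_fraction(calls: pd.DataFrame, by_replicate: bool = True) -> dict:
    """Amoeboid fraction among motile tracks: amoeboid / (amoeboid +
    non-amoeboid motile), non-motile excluded.

    With replicate labels the fraction is computed per replicate and
    summarized as grand mean +/- SEM across replicates; replicates with zero
    motile tracks are excluded with a warning.
    """
    if "label" not in calls:
        raise ValidationError("calls table must carry a 'label' column")
    motile = calls[calls["label"] != NON_MOTILE]
    if not by_replicate or "replicate" not in calls:
        if motile.empty:
            raise ValidationError("no motile tracks")
        frac = float((motile["label"] == AMOEBOID).mean())
        return {
            "fraction": frac,
            "sem": np.nan,
            "n_motile": int(len(motile)),
            "n_amoeboid": int((motile["label"] == AMOEBOID).sum()),
        }
    fracs = []
    for rep, grp in calls.groupby("replicate"):
        m = grp[grp["label"] != NON_MOTILE]
        if m.empty:
            log.warning("replicate %s has no motile tracks; excluded", rep)
            continue
        fracs.append((m["label"] == AMOEBOID).mean())
    if not fracs:
        raise ValidationError("no replicate with motile tracks")
    fracs = np.asarray(fracs, dtype=float)
    return {
        "fraction": float(fracs.mean()),
        "sem": float(fracs.std(ddof=1) / np.sqrt(fracs.size)) if fracs.size > 1 else np.nan,
        "n_motile": int(len(motile)),
        "n_amoeboid": int((motile["label"] == AMOEBOID).sum()),
        "replicate_fractions": fracs,
    }


def normalize_to_control(
    treatment: np.ndarray, control: np.ndarray, mode: str = "ratio"
) -> dict:
    """Normalize treatment values against the control-group mean.

    ``ratio`` mode divides by the control mean (requires it to be positive);
    ``difference`` mode subtracts it.  The mode is recorded in the output so
    downstream consumers can interpret the values.
    """
    treatment = np.atleast_1d(np.asarray(treatment, dtype=float))
    control = np.atleast_1d(np.asarray(control, dtype=float))
    if control.size == 0 or treatment.size == 0:
        raise ValidationError("treatment and control must be non-empty")
    cmean = float(control.mean())
    if mode == "ratio":
        if cmean <= 0:
            raise ValidationError(
                "control mean is not positive; use mode='difference' instead"
            )
        values = treatment / cmean
    elif mode == "difference":
        values = treatment - cmean
    else:
        raise ValidationError("mode must be 'ratio' or 'difference'")
    return {"values": values, "control_mean": cmean, "mode": mode}
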