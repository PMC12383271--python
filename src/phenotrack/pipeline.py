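"""End-to-end analysis: image stack -> tracks -> motility + shape features
-> phenotype calls.

This is the glue the CLI and the integration tests run: temporal-median
background removal, detection/linking/length-filtering, per-track speed and
persistence statistics, per-track eccentricity from local Otsu segmentation
at (a subsample of) the track's detections, and threshold classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, classify_tracks
from .motility import track_summary
from .shape import measure_cell, segment_cell
from .tracking import (
    TrackingConfig,
    detect_stack,
    filter_trajectories,
    link_trajectories,
    remove_background,
)

__all__ = ["track_eccentricities", "analyze_stack"]

log = logging.getLogger(__name__)


def track_eccentricities(
    cleaned: np.ndarray,
    tracks: pd.DataFrame,
    config: TrackingConfig | None = None,
    metric: str = "moment",
    pixel_size: float = 1.0,
    stride: int = 10,
) -> pd.DataFrame:
    """Per-frame eccentricity along each track, sampled every ``stride``
    detections, from Otsu segmentation of the background-removed frames.

    Returns tidy rows (track_id, frame, ecc, major_um, minor_um,
    orientation_rad, metric).  Frames whose segmentation fails are skipped.
    """
    config = config or TrackingConfig()
    window = 3 * config.particle_size
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        for row in grp.iloc[::stride].itertuples(index=False):
            mask = segment_cell(cleaned[int(row.frame)], row.x, row.y, window=window)
            if mask is None or mask.sum() < 5:
                continue
            fit = measure_cell(
                cleaned[int(row.frame)], mask, metric=metric, pixel_size=pixel_size
            )
            rows.append(
                {
                    "track_id": tid,
                    "frame": int(row.frame),
                    "ecc": fit.eccentricity,
                    "major_um": fit.major,
                    "minor_um": fit.minor,
                    "orientation_rad": fit.orientation,
                    "metric": fit.metric,
                }
            )
    return pd.DataFrame(rows)


def analyze_stack(
    stack: np.ndarray,
    fps: float,
    pixel_size: float,
    tracking: TrackingConfig | None = None,
    classifier: ClassifierConfig | None = None,
    replicate: str | None = None,
    ecc_stride: int = 10,
) -> dict:
    """Run the full pipeline on one video.

    Returns a dict with the filtered ``tracks`` table, the per-track
    ``summary`` (speed, persistence time, eccentricity) and the phenotype
    ``calls`` table, plus per-stage counts.
    """
    tracking = tracking or TrackingConfig()
    classifier = classifier or ClassifierConfig(ecc_metric="moment")

    cleaned = remove_background(stack)
    detections = detect_stack(cleaned, tracking)
    linked = link_trajectories(detections, tracking)
    tracks = filter_trajectories(linked, tracking)
    log.info(
        "pipeline counts: %d detections, %d linked tracks, %d after length filter",
        len(detections),
        linked["track_id"].nunique() if len(linked) else 0,
        tracks["track_id"].nunique() if len(tracks) else 0,
    )

    summary = track_summary(tracks, fps, pixel_size, replicate=replicate)
    shapes = track_eccentricities(
        cleaned,
        tracks,
        tracking,
        metric=classifier.ecc_metric,
        pixel_size=pixel_size,
        stride=ecc_stride,
    )
    if len(shapes):
        stat = "max" if classifier.ecc_statistic == "max" else "mean"
        ecc = shapes.groupby("track_id")["ecc"].agg(stat).rename("mean_ecc")
        summary = summary.merge(ecc, on="track_id", how="left")
    else:
        summary["mean_ecc"] = np.nan
    summary["mean_ecc"] = summary["mean_ecc"].fillna(0.0)

    calls = classify_tracks(summary, classifier)
    return {
        "tracks": tracks,
        "shapes": shapes,
        "summary": summary,
        "calls": calls,
        "n_detections": int(len(detections)),
        "n_tracks_linked": int(linked["track_id"].nunique()) if len(linked) else 0,
        "n_tracks_kept": int(tracks["track_id"].nunique()) if len(tracks) else 0,
    }
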