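"""Video tracking: temporal-median background removal, blob detection and
frame-to-frame linking.

The stage order and parameters follow standard single-particle tracking
practice for swimming microalgae: per-pixel absolute difference from the
temporal median isolates moving cells; detection is a difference-of-Gaussians
band-pass at the feature diameter followed by local-maximum picking,
sub-pixel centroid refinement and a keep-the-brighter minimum-separation
suppression; linking is per-frame optimal assignment under a maximum
per-frame displacement with a short disappearance memory.

Coordinate convention: 0-based frame indices; ``x`` is the column and ``y``
the row, both measured at pixel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .presets import ValidationError

__all__ = [
    "TrackingConfig",
    "remove_background",
    "detect_particles",
    "detect_stack",
    "link_trajectories",
    "filter_trajectories",
    "track_stack",
]

log = logging.getLogger(__name__)


@dataclass
class TrackingConfig:
    """Tracking parameters.

    ``particle_size`` is the feature *diameter* in pixels (odd), used to
    scale the band-pass and the refinement footprint.  ``min_separation``
    suppresses the dimmer of any detection pair closer than this distance.
    ``max_displacement`` bounds the linked displacement per elapsed frame and
    ``memory`` is the number of consecutive frames a cell may go undetected
    while keeping its identity.  Tracks with fewer than ``min_track_length``
    detections are discarded.
    """

    particle_size: int = 17
    min_separation: float = 51.0
    max_displacement: float = 17.0
    memory: int = 2
    min_track_length: int = 10
    threshold_percentile: float = 99.5
    min_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.particle_size < 3 or self.particle_size % 2 == 0:
            raise ValidationError("particle_size must be an odd integer >= 3")
        if min(self.min_separation, self.max_displacement) <= 0:
            raise ValidationError("min_separation and max_displacement must be > 0")
        if self.memory < 0 or self.min_track_length <= 0:
            raise ValidationError("memory >= 0 and min_track_length > 0 required")


def remove_background(stack: np.ndarray) -> np.ndarray:
    """Absolute difference of every pixel from its temporal median.

    ``stack`` has shape (frames, height, width); the result is float32 of the
    same shape.  The median is taken over the full clip, so static structure
    (background level, illumination gradients, debris) cancels exactly and
    only moving cells survive.  Processes row blocks to bound memory on long
    clips.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValidationError("need a (frames, height, width) stack with >= 3 frames")
    n_frames, height, width = stack.shape
    # float stacks keep their precision; camera-count (integer) stacks are
    # reduced to float32, which is exact for 8/16-bit data and halves memory
    out_dtype = np.float64 if stack.dtype == np.float64 else np.float32
    out = np.empty(stack.shape, dtype=out_dtype)
    # ~64 MB of scratch per block
    block = max(1, int(8e6 / (n_frames * width)))
    for r0 in range(0, height, block):
        r1 = min(r0 + block, height)
        chunk = stack[:, r0:r1, :].astype(out_dtype)
        med = np.median(chunk, axis=0)
        out[:, r0:r1, :] = np.abs(chunk - med)
    return out


def _bandpass(frame: np.ndarray, particle_size: int) -> tuple[np.ndarray, float]:
    """Band-pass scaled to the feature diameter: short-scale smoothing minus
    a local background at the feature size.  Returns the clipped band-pass
    image and a robust noise scale (MAD-based sigma of the unclipped
    residual; cell pixels are sparse enough not to perturb it)."""
    frame = np.asarray(frame, dtype=np.float32)
    smoothed = ndimage.gaussian_filter(frame, 1.0)
    background = ndimage.uniform_filter(frame, particle_size)
    residual = smoothed - background
    sigma = float(np.median(np.abs(residual - np.median(residual)))) / 0.6745
    return np.clip(residual, 0.0, None), sigma


def _refine(frame: np.ndarray, peaks: np.ndarray, radius: int) -> pd.DataFrame:
    """Sub-pixel refinement: intensity-weighted centroid inside a disc of
    ``radius`` pixels around each candidate maximum; also integrates mass and
    the radius of gyration."""
    h, w = frame.shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disc = (yy**2 + xx**2) <= radius**2
    rows = []
    for py, px in peaks:
        y0, y1 = py - radius, py + radius + 1
        x0, x1 = px - radius, px + radius + 1
        ys0, ys1 = max(y0, 0), min(y1, h)
        xs0, xs1 = max(x0, 0), min(x1, w)
        win = frame[ys0:ys1, xs0:xs1]
        m = disc[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
        weights = win * m
        mass = float(weights.sum())
        if mass <= 0:
            continue
        gy, gx = np.mgrid[ys0:ys1, xs0:xs1]
        cy = float((weights * gy).sum() / mass)
        cx = float((weights * gx).sum() / mass)
        rg = float(
            np.sqrt(((weights * ((gy - cy) ** 2 + (gx - cx) ** 2)).sum()) / mass)
        )
        rows.append((cx, cy, mass, rg))
    return pd.DataFrame(rows, columns=["x", "y", "mass", "size"])


def _suppress(dets: pd.DataFrame, min_separation: float) -> pd.DataFrame:
    """Greedy minimum-separation suppression keeping the brighter detection;
    equal brightness breaks ties toward lower (y, x)."""
    if len(dets) <= 1:
        return dets
    order = dets.sort_values(
        ["mass", "y", "x"], ascending=[False, True, True]
    ).index.to_numpy()
    kept: list[int] = []
    for idx in order:
        x, y = dets.at[idx, "x"], dets.at[idx, "y"]
        if all(
            np.hypot(x - dets.at[k, "x"], y - dets.at[k, "y"]) >= min_separation
            for k in kept
        ):
            kept.append(idx)
    return dets.loc[sorted(kept)].reset_index(drop=True)


def detect_particles(frame: np.ndarray, config: TrackingConfig) -> pd.DataFrame:
    """Detect cells in one background-removed frame.

    Returns a DataFrame with sub-pixel ``x, y`` (pixel-center convention),
    integrated ``mass`` and radius-of-gyration ``size``; may be empty.  All
    returned detections are at least ``min_separation`` apart.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if min(frame.shape) < config.particle_size:
        raise ValidationError("image smaller than particle_size")
    bp, sigma = _bandpass(frame, config.particle_size)
    if not np.any(bp > 0):
        return pd.DataFrame(columns=["x", "y", "mass", "size"])
    # The percentile alone fails on sparse scenes (cells cover far less than
    # 0.5% of the frame, so the percentile sits inside the noise); combine
    # it with a multiple of the robust noise scale.
    threshold = max(
        float(np.percentile(bp, config.threshold_percentile)), 6.0 * sigma, 1e-6
    )
    peaks = peak_local_max(
        bp, min_distance=max(config.particle_size // 2, 1), threshold_abs=threshold
    )
    if peaks.size == 0:
        return pd.DataFrame(columns=["x", "y", "mass", "size"])
    dets = _refine(bp, peaks, config.particle_size // 2)
    if config.min_mass > 0:
        dets = dets[dets["mass"] >= config.min_mass].reset_index(drop=True)
    return _suppress(dets, config.min_separation)


def detect_stack(stack: np.ndarray, config: TrackingConfig) -> pd.DataFrame:
    """Run :func:`detect_particles` on every frame; adds a ``frame`` column."""
    frames = []
    for f in range(stack.shape[0]):
        d = detect_particles(stack[f], config)
        d.insert(0, "frame", f)
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    log.info("detected %d particles in %d frames", len(out), stack.shape[0])
    return out


def link_trajectories(detections: pd.DataFrame, config: TrackingConfig) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    Per frame, candidate links between active tracks and new detections are
    resolved by optimal assignment on squared displacement; a link is valid
    only if the displacement per elapsed frame is at most
    ``max_displacement``.  A track missing for more than ``memory``
    consecutive frames is terminated.  Returns the input rows with a
    ``track_id`` column; every detection belongs to exactly one track.
    """
    if detections.empty:
        out = detections.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    if not detections["frame"].is_monotonic_increasing:
        detections = detections.sort_values("frame", kind="stable").reset_index(drop=True)

    track_ids = np.full(len(detections), -1, dtype=int)
    next_id = 0
    # active tracks: list of [track_id, last_frame, x, y]
    active: list[list[float]] = []
    big = 1e18
    for frame, idx in detections.groupby("frame").groups.items():
        idx = np.asarray(idx)
        xs = detections.loc[idx, "x"].to_numpy(float)
        ys = detections.loc[idx, "y"].to_numpy(float)
        active = [a for a in active if frame - a[1] <= config.memory + 1]
        assigned_det = np.zeros(len(idx), dtype=bool)
        if active:
            cost = np.full((len(active), len(idx)), big)
            for i, (_, last_f, ax, ay) in enumerate(active):
                gap = frame - last_f
                d2 = (xs - ax) ** 2 + (ys - ay) ** 2
                ok = d2 <= (config.max_displacement * gap) ** 2
                cost[i, ok] = d2[ok]
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= big:
                    continue
                tid = int(active[i][0])
                track_ids[idx[j]] = tid
                active[i] = [tid, frame, xs[j], ys[j]]
                assigned_det[j] = True
        for j in np.flatnonzero(~assigned_det):
            track_ids[idx[j]] = next_id
            active.append([next_id, frame, xs[j], ys[j]])
            next_id += 1
    out = detections.copy()
    out["track_id"] = track_ids
    return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def filter_trajectories(tracks: pd.DataFrame, config: TrackingConfig) -> pd.DataFrame:
    """Discard tracks with fewer detections than ``min_track_length``."""
    if tracks.empty:
        return tracks
    kept = tracks.groupby("track_id")["frame"].transform("size") >= config.min_track_length
    out = tracks[kept].reset_index(drop=True)
    log.info(
        "kept %d/%d tracks of length >= %d",
        out["track_id"].nunique(),
        tracks["track_id"].nunique(),
        config.min_track_length,
    )
    return out


def track_stack(stack: np.ndarray, config: TrackingConfig | None = None) -> pd.DataFrame:
    """Full tracking pipeline: background removal, detection, linking and
    length filtering.  Returns quality-filtered tracks."""
    config = config or TrackingConfig()
    cleaned = remove_background(stack)
    detections = detect_stack(cleaned, config)
    linked = link_trajectories(detections, config)
    return filter_trajectories(linked, config)
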