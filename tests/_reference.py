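"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive and algorithmically different from the
package: detection by global thresholding + connected components, linking by
exhaustive enumeration of assignments, smoothing by explicit sliding
polynomial fits, medians by sorting.  None of it imports from phenotrack's
internals beyond array in/out.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage


def ref_median_stack(stack: np.ndarray) -> np.ndarray:
    """Per-pixel temporal median by explicit sorting."""
    srt = np.sort(np.asarray(stack, dtype=float), axis=0)
    n = srt.shape[0]
    if n % 2:
        return srt[n // 2]
    return 0.5 * (srt[n // 2 - 1] + srt[n // 2])


def ref_detect(frame: np.ndarray, rel_threshold: float = 0.3, min_area: int = 5):
    """Threshold at ``rel_threshold * max`` and return intensity-weighted
    centroids (x, y) of connected components, brightest first."""
    frame = np.asarray(frame, dtype=float)
    if frame.max() <= 0:
        return []
    mask = frame > rel_threshold * frame.max()
    labels, n = ndimage.label(mask)
    out = []
    for lab in range(1, n + 1):
        sel = labels == lab
        if sel.sum() < min_area:
            continue
        w = frame * sel
        total = w.sum()
        gy, gx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        out.append(((w * gx).sum() / total, (w * gy).sum() / total, total))
    out.sort(key=lambda t: -t[2])
    return [(x, y) for x, y, _ in out]


def ref_suppress(candidates, min_separation):
    """Brute-force minimum-separation suppression: enumerate all pairs and
    apply the keep-brighter rule.  ``candidates`` are (x, y, mass)."""
    alive = list(candidates)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(alive, 2):
            if np.hypot(a[0] - b[0], a[1] - b[1]) < min_separation:
                loser = b if a[2] > b[2] else a if b[2] > a[2] else max(
                    a, b, key=lambda c: (c[1], c[0])
                )
                alive.remove(loser)
                changed = True
                break
    return alive


def ref_link(per_frame: list[list[tuple[float, float]]], max_disp: float, memory: int):
    """Exhaustive minimal-total-squared-displacement linking.

    ``per_frame[f]`` lists (x, y) detections of frame f.  For each frame all
    injective assignments of detections to active tracks are enumerated
    (feasible only for a handful of cells).  Returns a list of tracks, each
    a list of (frame, x, y).
    """
    tracks: list[list[tuple[int, float, float]]] = []
    active: list[int] = []
    for f, dets in enumerate(per_frame):
        active = [i for i in active if f - tracks[i][-1][0] <= memory + 1]
        # maximize the number of links, then minimize total squared cost
        best, best_cost = None, np.inf
        for k in range(min(len(active), len(dets)), 0, -1):
            for tr_subset in itertools.permutations(active, k):
                for det_subset in itertools.combinations(range(len(dets)), k):
                    cost, ok = 0.0, True
                    for ti, di in zip(tr_subset, det_subset):
                        lf, lx, ly = tracks[ti][-1]
                        d2 = (dets[di][0] - lx) ** 2 + (dets[di][1] - ly) ** 2
                        if np.sqrt(d2) > max_disp * (f - lf):
                            ok = False
                            break
                        cost += d2
                    if ok and cost < best_cost:
                        best, best_cost = list(zip(tr_subset, det_subset)), cost
            if best is not None:
                break
        matched_tracks, matched_dets = set(), set()
        if best is not None:
            for ti, di in best:
                tracks[ti].append((f, dets[di][0], dets[di][1]))
                matched_tracks.add(ti)
                matched_dets.add(di)
        for di, (x, y) in enumerate(dets):
            if di not in matched_dets:
                tracks.append([(f, x, y)])
                active.append(len(tracks) - 1)
    return tracks


def ref_savgol(values: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Sliding local least-squares polynomial fit evaluated pointwise."""
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        idx = np.arange(lo, lo + window)
        coeffs = np.polyfit(idx, values[idx], order)
        out[i] = np.polyval(coeffs, i)
    return out


def ref_unwrap(theta: np.ndarray) -> np.ndarray:
    """Minimal-jump angle unwrapping, one step at a time."""
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    for i in range(1, out.size):
        while out[i] - out[i - 1] > np.pi:
            out[i:] -= 2 * np.pi
        while out[i] - out[i - 1] < -np.pi:
            out[i:] += 2 * np.pi
    return out
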