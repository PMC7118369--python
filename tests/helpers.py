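"""Shared test utilities: truth matching and landmark measurement."""

from __future__ import annotations

import numpy as np
import pandas as pd

from intravital.core import MovieStack


def match_tracks_to_truth(
    metrics: pd.DataFrame, linked: pd.DataFrame, truth
) -> pd.DataFrame:
    """Match each analyzed track to the nearest ground-truth cell.

    Matching is by start-position distance (frame 0 detection vs frame 0
    true centroid), greedily in order of increasing distance, one truth
    cell per track.  Returns ``metrics`` with ``truth_cell`` plus the true
    labels joined in.
    """
    starts = (
        linked.sort_values("frame").groupby("track_id").first()[["x_um", "y_um"]]
    )
    track_ids = [t for t in metrics["track_id"] if t in starts.index]
    truth_pos = truth.trajectories[:, 0, :]
    pairs = []
    for tid in track_ids:
        p = starts.loc[tid].to_numpy(dtype=float)
        d = np.linalg.norm(truth_pos - p, axis=1)
        for ci in range(truth.n_cells):
            pairs.append((d[ci], tid, ci))
    pairs.sort()
    used_t, used_c = set(), set()
    assignment = {}
    for d, tid, ci in pairs:
        if tid in used_t or ci in used_c:
            continue
        used_t.add(tid)
        used_c.add(ci)
        assignment[tid] = ci
    out = metrics.copy()
    out["truth_cell"] = out["track_id"].map(assignment)
    out = out.dropna(subset=["truth_cell"])
    out["truth_cell"] = out["truth_cell"].astype(int)
    out["true_lgr5"] = truth.lgr5_state[out["truth_cell"]]
    out["true_migratory"] = truth.migratory_label[out["truth_cell"]]
    out["true_mode"] = truth.mode_label[out["truth_cell"]]
    return out


def measure_landmarks(
    stack: MovieStack, centers_px: np.ndarray, radius_px: float
) -> np.ndarray:
    """Intensity-weighted centroids (μm) of landmarks in every frame.

    ``centers_px`` is ``(n, 2)`` expected ``(x, y)`` positions in pixels;
    the centroid is measured in the RFP channel within a window of
    ``2 * radius_px`` around each expected position.
    Returns ``(n, n_frames, 2)`` in μm.
    """
    n = len(centers_px)
    out = np.zeros((n, stack.n_frames, 2))
    h, w = stack.frame_shape
    half = int(np.ceil(2 * radius_px))
    for t in range(stack.n_frames):
        img = stack.frame(t, "rfp").astype(float)
        for i, (cx, cy) in enumerate(centers_px):
            x0, x1 = int(cx) - half, int(cx) + half + 1
            y0, y1 = int(cy) - half, int(cy) + half + 1
            x0, x1 = max(0, x0), min(w, x1)
            y0, y1 = max(0, y0), min(h, y1)
            patch = img[y0:y1, x0:x1]
            yy, xx = np.mgrid[y0:y1, x0:x1]
            tot = patch.sum()
            out[i, t, 0] = (patch * xx).sum() / tot * stack.pixel_size_um
            out[i, t, 1] = (patch * yy).sum() / tot * stack.pixel_size_um
    return out


def exhaustive_best_shift(ref, moving, window: int, min_overlap: int = 64):
    """Brute-force argmax of overlap-Pearson over all shifts in a square
    window; the independent oracle for the greedy climb."""
    from intravital.registration import (
        DegenerateOverlapError,
        pearson_overlap,
        shift_image,
    )

    best = (-np.inf, (0, 0))
    for dx in range(-window, window + 1):
        for dy in range(-window, window + 1):
            try:
                r = pearson_overlap(
                    ref, shift_image(moving, dx, dy), min_overlap
                )
            except (DegenerateOverlapError, ValueError):
                continue
            if r > best[0]:
                best = (r, (dx, dy))
    return best[1], best[0]
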