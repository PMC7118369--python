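"""Cell detection, Lgr5 classification and frame-to-frame track linking.

Detection runs on the registered RFP channel (all tumor cells are RFP+);
the Lgr5 state of each detection is read out from the eGFP channel within
the detection footprint.  Linking is deterministic greedy nearest-neighbor
matching, processed in order of increasing pair distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .core import MovieStack

logger = logging.getLogger("intravital")

#: columns of a detection table
DETECTION_COLUMNS = (
    "frame", "x_um", "y_um", "diameter_um", "mean_rfp", "mean_gfp",
)

#: Default detection threshold: approximate minimum blob peak amplitude
#: above background, in intensity counts (12-bit scale).
DETECT_THRESHOLD = 1000.0


def detect_cells(
    rfp: np.ndarray,
    gfp: np.ndarray,
    pixel_size_um: float,
    diameter_range_um: tuple[float, float] = (10.0, 30.0),
    threshold: float = DETECT_THRESHOLD,
    frame: int = 0,
) -> pd.DataFrame:
    """Detect cells in one registered frame pair by scale-space blobs.

    Laplacian-of-Gaussian blob detection runs on the background-subtracted
    RFP channel within the expected diameter range.  The blob scale radius
    is taken as 2 sigma of the detected scale (the radius at which a
    Gaussian-profiled cell falls to e^-2 of its peak), so
    ``diameter_um = 2 x radius = 4 sigma``.  Centroids are refined to
    sub-pixel precision by intensity-weighted averaging inside the
    footprint; mean channel intensities are measured in a disk of the
    detected radius.

    An empty or blank frame yields an empty table, not an error.
    """
    rfp = np.asarray(rfp, dtype=float)
    gfp = np.asarray(gfp, dtype=float)
    if rfp.shape != gfp.shape:
        raise ValueError("rfp and gfp frames must have identical shape")
    d_lo, d_hi = diameter_range_um
    if not 0 < d_lo < d_hi:
        raise ValueError("diameter_range_um must be a positive interval")
    # flat-field: remove the smooth background pedestal before LoG
    bg = np.median(rfp)
    work = np.clip(rfp - bg, 0, None)
    sigma_lo = d_lo / 4.0 / pixel_size_um
    sigma_hi = d_hi / 4.0 / pixel_size_um
    blobs = blob_log(
        work,
        min_sigma=sigma_lo,
        max_sigma=sigma_hi,
        num_sigma=7,
        # a Gaussian blob of peak amplitude A has scale-normalized LoG
        # response ~A/2 at the matched scale; 0.4*A leaves headroom for
        # scale-grid mismatch while rejecting background texture
        threshold=0.4 * threshold,
        overlap=0.5,
    )
    rows = []
    h, w = rfp.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, sigma in blobs:
        radius_px = 2.0 * sigma
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
        if not disk.any():
            continue
        weights = work * disk
        total = weights.sum()
        if total > 0:  # sub-pixel refinement
            cx = float((weights * xx).sum() / total)
            cy = float((weights * yy).sum() / total)
        rows.append(
            {
                "frame": frame,
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "diameter_um": 2.0 * radius_px * pixel_size_um,
                "mean_rfp": float(rfp[disk].mean()),
                "mean_gfp": float(gfp[disk].mean()),
            }
        )
    det = pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))
    # flag probable under-segmentation: detections closer than one diameter
    if len(det) >= 2:
        pts = det[["x_um", "y_um"]].to_numpy()
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        mean_d = det["diameter_um"].mean()
        if (dmat.min() < mean_d) and mean_d > 0:
            logger.info(
                "frame %d: detections closer than one mean diameter "
                "(possible merge/split ambiguity)", frame,
            )
    return det


def detect_movie(
    stack: MovieStack,
    diameter_range_um: tuple[float, float] = (10.0, 30.0),
    threshold: float = DETECT_THRESHOLD,
) -> pd.DataFrame:
    """Run :func:`detect_cells` on every frame of a registered movie."""
    frames = [
        detect_cells(
            stack.frame(t, "rfp"),
            stack.frame(t, "gfp"),
            stack.pixel_size_um,
            diameter_range_um=diameter_range_um,
            threshold=threshold,
            frame=t,
        )
        for t in range(stack.n_frames)
    ]
    return pd.concat(frames, ignore_index=True)


#: contrast ratio between the Otsu classes below which the pooled eGFP
#: distribution is treated as unimodal (no separable bright population)
OTSU_MIN_CONTRAST = 2.0

#: absolute mean-eGFP floor (12-bit counts) used when the distribution is
#: unimodal: a movie of all-dark or all-bright cells has no valid Otsu split
GFP_FLOOR = 50.0


def classify_lgr5(
    detections: pd.DataFrame,
    gfp_threshold: float | str = "otsu",
    gfp_floor: float = GFP_FLOOR,
) -> tuple[pd.Series, float]:
    """Classify each detection's Lgr5 state from its mean eGFP intensity.

    ``lgr5 = mean_gfp > threshold``.  With ``gfp_threshold="otsu"`` the
    threshold is computed once per movie from the pooled ``mean_gfp``
    distribution of all detections (appropriate when the reporter is
    bimodal: eGFP-bright Lgr5+ cells vs eGFP-dark Lgr5- cells).  When the
    Otsu split shows no real contrast between its two classes (class-mean
    ratio below ``OTSU_MIN_CONTRAST``) the distribution is unimodal —
    a movie whose cells are all Lgr5- or all Lgr5+ — and the absolute
    ``gfp_floor`` is used instead, since Otsu would then split noise.

    Returns the boolean series and the threshold that was applied.
    """
    vals = detections["mean_gfp"].to_numpy(dtype=float)
    if gfp_threshold == "otsu":
        if len(detections) < 2:
            raise ValueError(
                "otsu thresholding needs >= 2 detections; "
                "pass a fixed numeric gfp_threshold instead"
            )
        # 4096 bins = native 12-bit resolution; coarse default binning can
        # collapse a tight intensity mode into one bin and return a
        # threshold inside it
        thr = float(threshold_otsu(vals, nbins=4096))
        lo, hi = vals[vals <= thr], vals[vals > thr]
        if len(lo) == 0 or len(hi) == 0 or hi.mean() < OTSU_MIN_CONTRAST * max(
            lo.mean(), 1e-9
        ):
            logger.info(
                "pooled eGFP distribution looks unimodal; using absolute "
                "floor %.0f instead of otsu %.1f", gfp_floor, thr,
            )
            thr = gfp_floor
    else:
        thr = float(gfp_threshold)
    return detections["mean_gfp"] > thr, thr


def link_tracks(
    detections: pd.DataFrame, max_link_um: float | None = None
) -> pd.DataFrame:
    """Link detections into tracks by distance-ordered greedy matching.

    For each consecutive frame pair, all candidate (track head, new
    detection) pairs within ``max_link_um`` are processed in order of
    increasing distance; each accepted pair extends a track, and pairs
    involving an already-matched endpoint are skipped.  Unmatched
    detections start new tracks; unmatched heads terminate.  Processing
    globally by distance (rather than per detection in table order) makes
    the assignment deterministic and order-invariant.

    ``max_link_um`` defaults to 1.5 x the mean detected diameter.

    Returns the detection table with ``track_id`` and ``lgr5_track``
    columns added (track-level Lgr5 state by majority vote; ties are
    called Lgr5+, conservative toward the rarer stem-cell class).
    """
    det = detections.reset_index(drop=True).copy()
    if det.empty:
        det["track_id"] = pd.Series(dtype=int)
        return det
    if max_link_um is None:
        max_link_um = 1.5 * float(det["diameter_um"].mean())

    det = det.sort_values(["frame", "x_um", "y_um"], kind="stable")
    det = det.reset_index(drop=True)
    track_id = np.full(len(det), -1, dtype=int)
    next_track = 0
    frames = sorted(det["frame"].unique())

    prev_idx = det.index[det["frame"] == frames[0]].to_numpy()
    for i in prev_idx:
        track_id[i] = next_track
        next_track += 1

    for fa, fb in zip(frames[:-1], frames[1:]):
        prev_idx = det.index[det["frame"] == fa].to_numpy()
        cur_idx = det.index[det["frame"] == fb].to_numpy()
        pa = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
        pb = det.loc[cur_idx, ["x_um", "y_um"]].to_numpy()
        pairs = []
        for ii, i in enumerate(prev_idx):
            for jj, j in enumerate(cur_idx):
                d = float(np.linalg.norm(pa[ii] - pb[jj]))
                if d <= max_link_um:
                    pairs.append((d, i, j))
        pairs.sort()
        used_prev: set[int] = set()
        used_cur: set[int] = set()
        for d, i, j in pairs:
            if i in used_prev or j in used_cur:
                continue
            used_prev.add(i)
            used_cur.add(j)
            track_id[j] = track_id[i]
        for j in cur_idx:
            if j not in used_cur:
                track_id[j] = next_track
                next_track += 1

    det["track_id"] = track_id
    # track-level Lgr5 state: majority vote over member detections
    if "lgr5" in det.columns:
        votes = det.groupby("track_id")["lgr5"].mean()
        ties = votes.index[votes == 0.5]
        if len(ties):
            logger.info(
                "%d track(s) with tied Lgr5 votes called Lgr5+", len(ties)
            )
        det["lgr5_track"] = det["track_id"].map(votes >= 0.5)
    return det


def track_table(linked: pd.DataFrame, n_frames: int) -> pd.DataFrame:
    """Per-track summary: length, completeness, mean diameter, Lgr5 state."""
    groups = linked.groupby("track_id")
    out = groups.agg(
        n_detections=("frame", "size"),
        first_frame=("frame", "min"),
        last_frame=("frame", "max"),
        mean_diameter_um=("diameter_um", "mean"),
    )
    out["complete"] = out["n_detections"] == n_frames
    if "lgr5_track" in linked.columns:
        out["lgr5"] = groups["lgr5_track"].first()
    return out.reset_index()
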