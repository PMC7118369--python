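"""Migration metrics: displacement, velocity, the half-diameter rule,
single-vs-cluster mode, and per-animal Lgr5- fractions.

A tracked cell is called *migratory* when its net displacement over a
4-hour window exceeds half a cell diameter (strict inequality).  Migratory
cells move either as *single* cells or as *clusters*, i.e. maintaining
cell-cell contact with at least one other migratory cell for a sustained
fraction of the window.  Group summaries are computed across animals (one
value per animal), not pooled over cells — the animal is the unit of
analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .stats import sem

logger = logging.getLogger("intravital")

#: default analysis window (hours)
WINDOW_H = 4.0

#: contact distance factor: centers within kappa * (r_i + r_j) touch
CONTACT_KAPPA = 1.2

#: fraction of window frames two cells must touch to count as a cluster
CONTACT_PERSISTENCE = 0.75


@dataclasses.dataclass
class TrackMetrics:
    """Motion metrics of one track over the analysis window."""

    track_id: int
    net_displacement_um: float
    path_length_um: float
    velocity_um_per_h: float
    duration_h: float
    diameter_um: float
    lgr5: bool
    migratory: bool = False
    mode: str = "not_migratory"  # single | cluster | not_migratory
    animal_id: str = ""
    movie_id: str = ""


def compute_metrics(
    track: pd.DataFrame,
    frame_interval_h: float,
    window_h: float = WINDOW_H,
    velocity_mode: str = "net",
) -> TrackMetrics | None:
    """Compute displacement/velocity metrics on the first 4-h sub-track.

    ``track`` is the per-frame table of one track (columns ``frame, x_um,
    y_um`` plus optional ``diameter_um``, ``lgr5_track``/``lgr5``,
    ``track_id``).  Metrics use the first ``window_h``-long stretch:
    net displacement is the Euclidean distance between the first and last
    window position, path length the sum of per-step lengths, and velocity
    ``net / window_h`` (set ``velocity_mode="path"`` for cumulative
    distance per hour; the choice is logged).

    A track spanning less than the window is excluded: returns ``None``
    with a logged reason, not an error.
    """
    track = track.sort_values("frame")
    k = int(round(window_h / frame_interval_h))
    if k < 1:
        raise ValueError("window shorter than one frame interval")
    frames = track["frame"].to_numpy()
    if len(frames) < k + 1 or frames[k] - frames[0] != k:
        tid = track["track_id"].iloc[0] if "track_id" in track.columns else "?"
        logger.info(
            "track %s excluded: spans %s consecutive frames (< %d needed "
            "for the %g h window)", tid, len(frames), k + 1, window_h,
        )
        return None
    pos = track[["x_um", "y_um"]].to_numpy()[: k + 1]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    path = float(steps.sum())
    if velocity_mode == "path":
        velocity = path / window_h
        logger.info("velocity computed as path length / time")
    else:
        velocity = net / window_h
    lgr5_col = "lgr5_track" if "lgr5_track" in track.columns else "lgr5"
    return TrackMetrics(
        track_id=int(track["track_id"].iloc[0]) if "track_id" in track.columns else -1,
        net_displacement_um=net,
        path_length_um=path,
        velocity_um_per_h=velocity,
        duration_h=window_h,
        diameter_um=float(track["diameter_um"].iloc[: k + 1].mean())
        if "diameter_um" in track.columns
        else np.nan,
        lgr5=bool(track[lgr5_col].iloc[0]) if lgr5_col in track.columns else False,
    )


def classify_migratory(
    net_displacement_um: float, cell_diameter_um: float
) -> bool:
    """Half-diameter rule: migratory iff displacement > 0.5 x diameter.

    The inequality is strict: a cell that moves exactly half a diameter
    in 4 h is *not* migratory.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter_um must be positive")
    return net_displacement_um > 0.5 * cell_diameter_um


def classify_mode(
    linked: pd.DataFrame,
    migratory_track_ids: list[int],
    frame_interval_h: float,
    window_h: float = WINDOW_H,
    kappa: float = CONTACT_KAPPA,
    persistence: float = CONTACT_PERSISTENCE,
) -> dict[int, str]:
    """Label each migratory track ``single`` or ``cluster``.

    Two migratory cells are in contact in a frame when their center
    distance is at most ``kappa * (r_i + r_j)`` (radii from the tracks'
    mean detected diameters); contact is symmetric.  A track is a
    ``cluster`` when it is in contact with at least one other migratory
    track in at least ``persistence`` of the window frames, else
    ``single``.
    """
    mig = set(int(t) for t in migratory_track_ids)
    if not mig:
        return {}
    k = int(round(window_h / frame_interval_h))
    radii = (
        linked[linked["track_id"].isin(mig)]
        .groupby("track_id")["diameter_um"]
        .mean()
        / 2.0
    )
    window = linked[
        linked["track_id"].isin(mig) & (linked["frame"] <= linked["frame"].min() + k)
    ]
    frames = sorted(window["frame"].unique())
    contact_frames: dict[tuple[int, int], int] = {}
    for f in frames:
        sub = window[window["frame"] == f]
        ids = sub["track_id"].to_numpy()
        pts = sub[["x_um", "y_um"]].to_numpy()
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i, j = int(ids[a]), int(ids[b])
                limit = kappa * (radii[i] + radii[j])
                if np.linalg.norm(pts[a] - pts[b]) <= limit:
                    key = (min(i, j), max(i, j))
                    contact_frames[key] = contact_frames.get(key, 0) + 1
    need = persistence * len(frames)
    clustered: set[int] = set()
    for (i, j), count in contact_frames.items():
        if count >= need:
            clustered.add(i)
            clustered.add(j)
    return {t: ("cluster" if t in clustered else "single") for t in mig}


def aggregate_by_animal(
    metrics: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Per-animal migration summaries and the across-animal group summary.

    ``metrics`` needs columns ``animal_id, migratory, lgr5, mode``.  For
    each animal the fractions (Lgr5-, single, cluster) are computed over
    its migratory tracks only; animals without migratory tracks are
    excluded from the fractions and logged.  The group summary is the mean
    +/- SEM *across animal-level values*, not pooled over cells.
    """
    required = {"animal_id", "migratory", "lgr5"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table needs columns {sorted(required)}")
    rows = []
    for animal, sub in metrics.groupby("animal_id"):
        mig = sub[sub["migratory"]]
        if mig.empty:
            logger.info("animal %s has no migratory tracks; excluded", animal)
            continue
        row = {
            "animal_id": animal,
            "n_tracks": len(sub),
            "n_migratory": len(mig),
            "fraction_lgr5neg": float((~mig["lgr5"].astype(bool)).mean()),
        }
        if "mode" in metrics.columns:
            row["fraction_single"] = float((mig["mode"] == "single").mean())
            row["fraction_cluster"] = float((mig["mode"] == "cluster").mean())
        rows.append(row)
    per_animal = pd.DataFrame(rows)
    summary: dict = {
        "n_animals": len(per_animal),
        "n_migratory_events": int(per_animal["n_migratory"].sum())
        if len(per_animal)
        else 0,
    }
    for col in ("fraction_lgr5neg", "fraction_single", "fraction_cluster"):
        if col in per_animal.columns and len(per_animal):
            vals = per_animal[col].to_numpy()
            summary[f"mean_{col}"] = float(vals.mean())
            summary[f"sem_{col}"] = sem(vals) if len(vals) >= 2 else np.nan
    return per_animal, summary
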