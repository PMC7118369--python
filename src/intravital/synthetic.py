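"""Seeded synthetic two-channel movies and lesion tables with ground truth.

The generator emulates the statistical structure of intravital two-photon
time-lapse data of a fluorescent colorectal tumor model: every tumor cell
carries a constitutive RFP label, the Lgr5-positive stem-cell subset
additionally expresses eGFP, frames are acquired hourly over a 4–8 h
window in 12 bit, and the whole field drifts rigidly from frame to frame.
Cells are rendered as isotropic 2D Gaussian blobs (sigma = diameter / 4)
on a smooth positive background texture; drift is an integer-pixel rigid
translation applied to all content of a frame; noise is additive zero-mean
Gaussian, clipped to the bit-depth range.

Everything the downstream pipeline estimates — per-frame drift, cell
trajectories, Lgr5 state, migratory and single/cluster labels, and the
diameter-dependent lesion composition rule — is returned as ground truth,
so each analysis stage is testable without any animal data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ConfigurationError, MovieStack

logger = logging.getLogger("intravital")

#: Peak blob intensity (12-bit counts) for both channels.
BLOB_AMPLITUDE = 2500.0

#: Default plasticity-threshold configuration of the lesion simulator:
#: below L* a lesion contains Lgr5+ cells with probability p0, above L*
#: always (step rule); single-cell-scale lesions are always Lgr5-negative.
DEFAULT_LESION_THRESHOLD_UM = 80.0
DEFAULT_P0_BELOW = 0.4


@dataclasses.dataclass
class SimConfig:
    """Configuration of a synthetic intravital movie.

    Defaults follow the acquisition the generator emulates: hourly frames
    over a 4-h window (5 frames), 12-bit intensities, ~20 μm tumor cells,
    and a slow integer-pixel random-walk drift.
    """

    image_height_px: int = 384
    image_width_px: int = 384
    pixel_size_um: float = 1.0
    n_frames: int = 5
    frame_interval_h: float = 1.0
    n_static_cells: int = 8
    n_migratory_cells: int = 6
    n_cluster_events: int = 1
    p_lgr5pos_overall: float = 0.3
    p_neg_among_migratory: float = 0.9
    cell_diameter_mean_um: float = 20.0
    cell_diameter_sd_um: float = 2.0
    migratory_step_um_per_frame: float = 5.0
    drift_max_step_px: int = 2
    drift_shifts: list[tuple[int, int]] | None = None  # explicit override
    static_jitter_frac: float = 0.01  # per-frame jitter sd / cell diameter
    noise_sd: float = 20.0
    background_level: float = 300.0
    bit_depth: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.frame_interval_h <= 0:
            raise ConfigurationError("frame_interval_h must be positive")
        for name in ("n_static_cells", "n_migratory_cells", "n_cluster_events"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("p_lgr5pos_overall", "p_neg_among_migratory"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.cell_diameter_mean_um <= 0:
            raise ConfigurationError("cell_diameter_mean_um must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ConfigurationError("noise_sd/background_level must be >= 0")
        if self.drift_shifts is not None:
            if len(self.drift_shifts) != self.n_frames:
                raise ConfigurationError("drift_shifts must have n_frames entries")
            if tuple(self.drift_shifts[0]) != (0, 0):
                raise ConfigurationError("drift of frame 0 must be (0, 0)")

    @property
    def n_cells(self) -> int:
        return self.n_static_cells + self.n_migratory_cells + 2 * self.n_cluster_events

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclasses.dataclass
class LesionRule:
    """Step rule the lesion simulator draws composition from."""

    threshold_um: float = DEFAULT_LESION_THRESHOLD_UM
    p0_below: float = DEFAULT_P0_BELOW
    single_cell_scale_um: float = 20.0  # lesions at/below this are Lgr5-


@dataclasses.dataclass
class GroundTruth:
    """Generator-side truth recovered by the downstream stages.

    ``trajectories`` are drift-free centroids in μm, shape
    ``(n_cells, n_frames, 2)`` with columns ``(x, y)``; the rendered
    position of cell ``i`` in raw frame ``t`` is
    ``trajectories[i, t] / pixel_size + true_shifts[t]`` (pixels).
    """

    true_shifts: np.ndarray  # (T, 2) int px, frame 0 = (0, 0)
    trajectories: np.ndarray  # (n_cells, T, 2) float um
    diameters_um: np.ndarray  # (n_cells,)
    lgr5_state: np.ndarray  # (n_cells,) bool
    migratory_label: np.ndarray  # (n_cells,) bool
    mode_label: np.ndarray  # (n_cells,) str: single|cluster|'' (non-migratory)
    cluster_id: np.ndarray  # (n_cells,) int, -1 for non-cluster cells
    lesion_rule: LesionRule | None = None

    @property
    def n_cells(self) -> int:
        return self.trajectories.shape[0]

    def to_frame(self, frame_interval_h: float = 1.0) -> pd.DataFrame:
        """Long-format table: one row per cell per frame."""
        rows = []
        n_frames = self.trajectories.shape[1]
        for i in range(self.n_cells):
            for t in range(n_frames):
                rows.append(
                    {
                        "cell_id": i,
                        "frame": t,
                        "time_h": t * frame_interval_h,
                        "x_um": self.trajectories[i, t, 0],
                        "y_um": self.trajectories[i, t, 1],
                        "lgr5": bool(self.lgr5_state[i]),
                        "migratory": bool(self.migratory_label[i]),
                        "mode": self.mode_label[i],
                    }
                )
        return pd.DataFrame(rows)


def _place_cells(
    rng: np.random.Generator,
    n: int,
    h_um: float,
    w_um: float,
    margin_um: float,
    min_sep_um: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` positions with pairwise separation >= min_sep."""
    if w_um - 2 * margin_um <= 0 or h_um - 2 * margin_um <= 0:
        raise ConfigurationError(
            "frame too small for the requested cells, diameters and drift: "
            "cells would be initialized (partly) outside the frame"
        )
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {n} cells with {min_sep_um} um separation; "
                "reduce density or enlarge the frame"
            )
        p = np.array(
            [
                rng.uniform(margin_um, w_um - margin_um),
                rng.uniform(margin_um, h_um - margin_um),
            ]
        )
        if all(np.linalg.norm(p - q) >= min_sep_um for q in placed):
            placed.append(p)
    return np.array(placed).reshape(n, 2)


def _render_blob(
    canvas: np.ndarray, cx_px: float, cy_px: float, sigma_px: float, amp: float
) -> None:
    """Add an isotropic Gaussian blob to ``canvas`` in place."""
    h, w = canvas.shape
    half = max(1, int(np.ceil(4 * sigma_px)))
    x0, x1 = int(np.floor(cx_px)) - half, int(np.floor(cx_px)) + half + 1
    y0, y1 = int(np.floor(cy_px)) - half, int(np.floor(cy_px)) + half + 1
    x0c, x1c = max(0, x0), min(w, x1)
    y0c, y1c = max(0, y0), min(h, y1)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - cx_px
    ys = np.arange(y0c, y1c) - cy_px
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
    canvas[y0c:y1c, x0c:x1c] += amp * g


def generate_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic drifted two-channel movie with full ground truth.

    Deterministic given ``config.seed``: identical configurations yield
    bit-identical movies and tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    px = config.pixel_size_um
    n_frames = config.n_frames

    # --- drift ---------------------------------------------------------
    if config.drift_shifts is not None:
        true_shifts = np.array(config.drift_shifts, dtype=int)
    else:
        steps = rng.integers(
            -config.drift_max_step_px,
            config.drift_max_step_px + 1,
            size=(n_frames - 1, 2),
        )
        true_shifts = np.vstack([[0, 0], np.cumsum(steps, axis=0)]).astype(int)
    max_shift = int(np.abs(true_shifts).max()) if n_frames else 0
    if max_shift > 0.5 * min(h, w):
        logger.warning(
            "drift (max |shift| = %d px) pushes more than half the frame "
            "content out of view",
            max_shift,
        )

    # --- cell bookkeeping ----------------------------------------------
    n_single_mig = config.n_migratory_cells
    n_cluster_cells = 2 * config.n_cluster_events
    n_cells = config.n_static_cells + n_single_mig + n_cluster_cells

    diameters = rng.normal(
        config.cell_diameter_mean_um, config.cell_diameter_sd_um, size=n_cells
    )
    diameters = np.clip(diameters, 4 * px, None)

    migratory = np.zeros(n_cells, dtype=bool)
    migratory[config.n_static_cells :] = True
    mode = np.array([""] * n_cells, dtype=object)
    mode[config.n_static_cells : config.n_static_cells + n_single_mig] = "single"
    mode[config.n_static_cells + n_single_mig :] = "cluster"
    cluster_id = np.full(n_cells, -1, dtype=int)
    for e in range(config.n_cluster_events):
        i = config.n_static_cells + n_single_mig + 2 * e
        cluster_id[i] = cluster_id[i + 1] = e

    # Lgr5 state: migratory events are Lgr5- with p_neg_among_migratory
    # (cluster partners share one draw: one escape event, one phenotype);
    # static cells are Lgr5+ with the overall stem-cell fraction.
    lgr5 = np.zeros(n_cells, dtype=bool)
    lgr5[: config.n_static_cells] = (
        rng.random(config.n_static_cells) < config.p_lgr5pos_overall
    )
    for i in range(config.n_static_cells, config.n_static_cells + n_single_mig):
        lgr5[i] = rng.random() >= config.p_neg_among_migratory
    for e in range(config.n_cluster_events):
        i = config.n_static_cells + n_single_mig + 2 * e
        state = rng.random() >= config.p_neg_among_migratory
        lgr5[i] = lgr5[i + 1] = state

    # --- trajectories (drift-free μm coordinates) ----------------------
    # Margin keeps every blob footprint inside the frame at every time
    # point, for all drifts and the full migratory excursion.
    excursion = config.migratory_step_um_per_frame * (n_frames - 1)
    n_anchor = config.n_static_cells + n_single_mig + config.n_cluster_events
    if n_anchor > 0:
        margin = max_shift * px + diameters.max() + excursion
        anchors = _place_cells(
            rng,
            n_anchor,
            h * px,
            w * px,
            margin_um=margin,
            min_sep_um=2.0 * config.cell_diameter_mean_um + excursion,
        )
    else:
        anchors = np.zeros((0, 2))

    traj = np.zeros((n_cells, n_frames, 2))
    # static cells: total jitter < 0.1 cell diameter
    for i in range(config.n_static_cells):
        jitter = rng.normal(
            0, config.static_jitter_frac * diameters[i], size=(n_frames, 2)
        )
        traj[i] = anchors[i] + jitter
    # singly migratory cells: constant heading plus small angular jitter
    for k in range(n_single_mig):
        i = config.n_static_cells + k
        traj[i] = _migrate(
            rng, anchors[config.n_static_cells + k],
            config.migratory_step_um_per_frame, n_frames,
        )
    # cluster events: two cells co-moving at fixed sub-contact separation
    for e in range(config.n_cluster_events):
        i = config.n_static_cells + n_single_mig + 2 * e
        anchor = anchors[config.n_static_cells + n_single_mig + e]
        lead = _migrate(
            rng, anchor, config.migratory_step_um_per_frame, n_frames
        )
        sep = 0.8 * (diameters[i] / 2 + diameters[i + 1] / 2)
        angle = rng.uniform(0, 2 * np.pi)
        offset = sep * np.array([np.cos(angle), np.sin(angle)])
        traj[i] = lead
        traj[i + 1] = lead + offset

    # --- rendering ------------------------------------------------------
    # Background: a static smooth positive texture that translates with the
    # drift (mimicking dim tissue autofluorescence), built on an oversized
    # canvas so every drifted crop stays fully defined.
    pad = max_shift
    texture = gaussian_filter(
        rng.standard_normal((h + 2 * pad, w + 2 * pad)), sigma=1.5
    )
    if texture.std() > 0:
        texture = (texture - texture.mean()) / texture.std()
    bg_canvas = config.background_level * np.clip(1.0 + 0.3 * texture, 0.1, None)

    data = np.zeros((n_frames, 2, h, w), dtype=np.uint16)
    for t in range(n_frames):
        dx, dy = true_shifts[t]
        rfp = bg_canvas[pad - dy : pad - dy + h, pad - dx : pad - dx + w].copy()
        gfp = np.zeros((h, w))
        for i in range(n_cells):
            cx = traj[i, t, 0] / px + dx
            cy = traj[i, t, 1] / px + dy
            sigma = diameters[i] / 4.0 / px
            _render_blob(rfp, cx, cy, sigma, BLOB_AMPLITUDE)
            if lgr5[i]:
                _render_blob(gfp, cx, cy, sigma, BLOB_AMPLITUDE)
        if config.noise_sd > 0:
            rfp = rfp + rng.normal(0, config.noise_sd, size=(h, w))
            gfp = gfp + rng.normal(0, config.noise_sd, size=(h, w))
        data[t, 0] = np.clip(np.rint(rfp), 0, config.max_intensity)
        data[t, 1] = np.clip(np.rint(gfp), 0, config.max_intensity)

    stack = MovieStack(
        data=data,
        pixel_size_um=px,
        frame_interval_h=config.frame_interval_h,
        channels=("rfp", "gfp"),
        bit_depth=config.bit_depth,
    )
    truth = GroundTruth(
        true_shifts=true_shifts,
        trajectories=traj,
        diameters_um=diameters,
        lgr5_state=lgr5,
        migratory_label=migratory,
        mode_label=np.asarray(mode, dtype=object),
        cluster_id=cluster_id,
    )
    return stack, truth


def _migrate(
    rng: np.random.Generator,
    start: np.ndarray,
    step_um: float,
    n_frames: int,
    heading_jitter_rad: float = 0.1,
) -> np.ndarray:
    """Constant-heading walk with small angular jitter per frame."""
    heading = rng.uniform(0, 2 * np.pi)
    pos = np.zeros((n_frames, 2))
    pos[0] = start
    for t in range(1, n_frames):
        heading += rng.normal(0, heading_jitter_rad)
        pos[t] = pos[t - 1] + step_um * np.array(
            [np.cos(heading), np.sin(heading)]
        )
    return pos


def generate_lesion_table(
    n_lesions: int,
    diameter_range_um: tuple[float, float] = (10.0, 300.0),
    threshold_um: float = DEFAULT_LESION_THRESHOLD_UM,
    p0_below: float = DEFAULT_P0_BELOW,
    seed: int = 0,
    single_cell_scale_um: float = 20.0,
) -> tuple[pd.DataFrame, LesionRule]:
    """Simulate a metastatic-lesion table under the step composition rule.

    Diameters are uniform on ``diameter_range_um``.  A lesion contains
    Lgr5+ cells with probability 1 above the plasticity threshold ``L*``
    and with probability ``p0_below`` otherwise — except lesions at
    single-cell scale (diameter <= ``single_cell_scale_um``), which are
    always Lgr5-negative, matching the observation that every single-cell
    metastasis is composed of Lgr5- cells only.

    Returns a table with columns ``lesion_id, diameter_um, contains_lgr5``
    and the :class:`LesionRule` used, for ground-truth comparison.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    lo, hi = diameter_range_um
    if lo <= 0 or hi <= lo:
        raise ValueError("diameter_range_um must be a positive interval")
    if not 0.0 <= p0_below <= 1.0:
        raise ValueError("p0_below must be in [0, 1]")
    rng = np.random.default_rng(seed)
    diameters = rng.uniform(lo, hi, size=n_lesions)
    u = rng.random(n_lesions)
    contains = np.where(
        diameters <= single_cell_scale_um,
        False,
        np.where(diameters > threshold_um, True, u < p0_below),
    )
    table = pd.DataFrame(
        {
            "lesion_id": np.arange(n_lesions),
            "diameter_um": diameters,
            "contains_lgr5": contains.astype(bool),
        }
    )
    rule = LesionRule(
        threshold_um=threshold_um,
        p0_below=p0_below,
        single_cell_scale_um=single_cell_scale_um,
    )
    return table, rule
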