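"""Metastatic-lesion scoring: size, Lgr5 composition and the plasticity
threshold.

Lesions in 2D liver-section images are connected components of the RFP
(all-tumor-cell) channel; a lesion *contains Lgr5+ cells* when enough GFP-
positive pixels fall inside its footprint.  Lesions are grouped per
diameter range, and the *plasticity threshold* D* is the smallest observed
diameter above which every lesion contains Lgr5+ cells — the size at which
Lgr5- founded lesions have invariably regained an Lgr5+ stem-cell pool.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

logger = logging.getLogger("intravital")

#: default diameter bin edges (μm); chosen to straddle the 80-μm threshold
DEFAULT_BIN_EDGES_UM = (0.0, 20.0, 40.0, 80.0, 160.0, 320.0)

#: minimum GFP-positive pixels for a lesion to count as containing Lgr5+
#: cells (rejects shot noise)
MIN_GFP_PIXELS = 5


@dataclasses.dataclass
class LesionRecord:
    lesion_id: int
    diameter_um: float
    contains_lgr5: bool
    animal_id: str = ""
    area_um2: float | None = None
    n_gfp_pixels: int | None = None


def score_image(
    rfp: np.ndarray,
    gfp: np.ndarray,
    pixel_size_um: float,
    rfp_threshold: float = 200.0,
    gfp_threshold: float = 200.0,
    min_area_um2: float | None = None,
    min_gfp_pixels: int = MIN_GFP_PIXELS,
    cell_diameter_um: float = 20.0,
    animal_id: str = "",
) -> pd.DataFrame:
    """Score one two-channel section image into a lesion table.

    Lesions are connected components of ``rfp > rfp_threshold`` with area
    at least ``min_area_um2`` (default: the area of one cell of mean
    diameter).  The lesion diameter is the equivalent-circle diameter
    ``2 * sqrt(area / pi)``; a lesion contains Lgr5+ cells when at least
    ``min_gfp_pixels`` pixels inside its footprint exceed
    ``gfp_threshold``.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size must be known and positive")
    rfp = np.asarray(rfp)
    gfp = np.asarray(gfp)
    if rfp.shape != gfp.shape:
        raise ValueError("rfp and gfp images must have identical shape")
    if min_area_um2 is None:
        min_area_um2 = np.pi * (cell_diameter_um / 2.0) ** 2
    px_area = pixel_size_um**2
    labeled = label(rfp > rfp_threshold, connectivity=2)
    gfp_pos = gfp > gfp_threshold
    rows = []
    for region in regionprops(labeled):
        area_um2 = region.area * px_area
        if area_um2 < min_area_um2:
            continue
        mask = labeled == region.label
        n_gfp = int(np.count_nonzero(gfp_pos & mask))
        rows.append(
            {
                "lesion_id": len(rows),
                "animal_id": animal_id,
                "diameter_um": 2.0 * np.sqrt(area_um2 / np.pi),
                "area_um2": area_um2,
                "n_gfp_pixels": n_gfp,
                "contains_lgr5": n_gfp >= min_gfp_pixels,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "animal_id", "diameter_um", "area_um2",
            "n_gfp_pixels", "contains_lgr5",
        ],
    )


def bin_composition(
    lesions: pd.DataFrame,
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM,
) -> pd.DataFrame:
    """Group lesions per diameter range and tabulate composition.

    Bins are half-open ``[lo, hi)`` over strictly increasing edges; a
    lesion outside every bin is counted in an ``overflow`` bin and logged.
    Per non-empty bin the Lgr5--only and contains-Lgr5+ fractions sum
    to 1, and the per-bin counts (including overflow) sum to the number
    of lesions.
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d = lesions["diameter_um"].to_numpy(dtype=float)
    pos = lesions["contains_lgr5"].to_numpy(dtype=bool)
    idx = np.digitize(d, edges) - 1  # -1 below first edge; len-1 at/after last
    overflow = (idx < 0) | (idx >= len(edges) - 1)
    if overflow.any():
        logger.info("%d lesion(s) outside all bins -> overflow", overflow.sum())
    rows = []
    for b in range(len(edges) - 1):
        in_bin = (idx == b) & ~overflow
        n = int(in_bin.sum())
        n_pos = int(pos[in_bin].sum())
        rows.append(
            {
                "bin_lo_um": edges[b],
                "bin_hi_um": edges[b + 1],
                "n_lesions": n,
                "n_contains_lgr5": n_pos,
                "n_lgr5neg_only": n - n_pos,
                "fraction_contains_lgr5": n_pos / n if n else np.nan,
                "fraction_lgr5neg_only": (n - n_pos) / n if n else np.nan,
            }
        )
    n_over = int(overflow.sum())
    rows.append(
        {
            "bin_lo_um": edges[-1],
            "bin_hi_um": np.inf,
            "n_lesions": n_over,
            "n_contains_lgr5": int(pos[overflow].sum()),
            "n_lgr5neg_only": n_over - int(pos[overflow].sum()),
            "fraction_contains_lgr5": pos[overflow].mean() if n_over else np.nan,
            "fraction_lgr5neg_only": (~pos[overflow]).mean() if n_over else np.nan,
        }
    )
    return pd.DataFrame(rows)


def plasticity_threshold(
    lesions: pd.DataFrame,
) -> tuple[float | None, int, int]:
    """Smallest observed diameter above which every lesion contains Lgr5+.

    Returns ``(D_star_um, n_above, n_violations_above)``.  ``D_star`` is
    ``None`` when the largest lesion is Lgr5--only (no such diameter
    exists in the observed set); when every lesion contains Lgr5+ cells,
    ``D_star`` is the smallest observed diameter.  ``n_violations_above``
    is always 0 by construction and is reported for audit symmetry.
    """
    if lesions.empty:
        raise ValueError("empty lesion table")
    d = lesions["diameter_um"].to_numpy(dtype=float)
    pos = lesions["contains_lgr5"].to_numpy(dtype=bool)
    if pos.all():
        d_star = float(d.min())
    else:
        neg_max = float(d[~pos].max())
        if neg_max >= d.max():
            return None, 0, 0
        d_star = neg_max
    above = d > d_star
    return d_star, int(above.sum()), int((~pos[above]).sum())
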