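"""Subset composition statistics, overall and per Desmin zone.

Produces the per-image composition table: for each macrophage subset the
count and percentage of all (non-excluded) macrophages, and the split of
each subset between Desmin-high and Desmin-low zones.  Cells whose centroid
falls in an excluded (vessel) region are dropped from every percentage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classification import CLASS_LABELS
from .zoning import LABEL_EXCLUDED, LABEL_HI, LABEL_LO, ZoneMap

logger = logging.getLogger(__name__)

ZONE_NAMES = {LABEL_EXCLUDED: "excluded", LABEL_LO: "Lo", LABEL_HI: "Hi"}


def assign_zones(features: pd.DataFrame, zonemap: ZoneMap,
                 mode: str = "centroid") -> pd.DataFrame:
    """Attach a zone label to every cell.

    ``centroid`` mode (default) reads the zone-map label at the rounded
    centroid pixel.  ``majority`` mode is available for callers that carry
    detection masks and is implemented in :func:`assign_zones_majority`.
    """
    if mode != "centroid":
        raise ValueError("use assign_zones_majority for majority-overlap mode")
    out = features.copy()
    nrows, ncols = zonemap.labels.shape
    zones = []
    for row, col in zip(out["centroid_row"], out["centroid_col"]):
        r, c = int(round(row)), int(round(col))
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ValueError(f"cell centroid ({row}, {col}) outside image")
        zones.append(ZONE_NAMES[int(zonemap.labels[r, c])])
    out["zone"] = pd.Series(zones, index=out.index, dtype=object)
    return out


def assign_zones_majority(features: pd.DataFrame, detections, zonemap: ZoneMap
                          ) -> pd.DataFrame:
    """Majority-overlap zone assignment (ties break toward the higher label)."""
    out = features.copy()
    by_id = {det.cell_id: det for det in detections}
    zones = []
    for cell_id in out["cell_id"]:
        det = by_id[int(cell_id)]
        r0, c0 = det.offset
        h, w = det.mask.shape
        region = zonemap.labels[r0:r0 + h, c0:c0 + w][det.mask]
        counts = np.bincount(region, minlength=3)
        zones.append(ZONE_NAMES[int(np.flatnonzero(counts == counts.max())[-1])])
    out["zone"] = pd.Series(zones, index=out.index, dtype=object)
    return out


def quantify_composition(features: pd.DataFrame, image_id: str = "image"
                         ) -> pd.DataFrame:
    """Tabulate subset composition per zone.

    Returns one row per (zone in {all, Hi, Lo}) x class with columns
    ``count``, ``pct_of_total_macs`` (zone ``all`` only: share of each
    subset among all non-excluded macrophages) and ``pct_of_class_in_zone``
    (Hi/Lo rows: share of that subset falling in the zone).  A class with
    zero cells reports missing (NaN) percentages, never 0.  The number of
    vessel-excluded cells is carried in ``n_excluded``.
    """
    if "class_label" not in features.columns or "zone" not in features.columns:
        raise ValueError("features must carry class_label and zone columns")
    excluded = features["zone"] == "excluded"
    n_excluded = int(excluded.sum())
    kept = features.loc[~excluded]
    total = len(kept)
    if total == 0:
        logger.warning("image %s: zero non-excluded cells; percentages are "
                       "missing", image_id)

    class_counts = {c: int((kept["class_label"] == c).sum()) for c in CLASS_LABELS}
    zone_counts = {
        (c, z): int(((kept["class_label"] == c) & (kept["zone"] == z)).sum())
        for c in CLASS_LABELS for z in ("Hi", "Lo")
    }

    rows = []
    for c in CLASS_LABELS:
        n_c = class_counts[c]
        rows.append({
            "image_id": image_id, "zone": "all", "class_label": c,
            "count": n_c,
            "pct_of_total_macs": 100.0 * n_c / total if total else np.nan,
            "pct_of_class_in_zone": np.nan,
            "n_excluded": n_excluded,
        })
    for z in ("Hi", "Lo"):
        for c in CLASS_LABELS:
            n_c = class_counts[c]
            n_cz = zone_counts[(c, z)]
            rows.append({
                "image_id": image_id, "zone": z, "class_label": c,
                "count": n_cz,
                "pct_of_total_macs": np.nan,
                "pct_of_class_in_zone": 100.0 * n_cz / n_c if n_c else np.nan,
                "n_excluded": n_excluded,
            })
    return pd.DataFrame(rows)
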