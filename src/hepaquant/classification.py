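"""Marker-based classification of detected macrophages.

Each detection gets per-channel mean intensities, then a hierarchical gate
assigns one of three subsets:

* ``ResKC``   — CLEC4F>=theta_C4 and TIM4>=theta_T4 (resident Kupffer cell)
* ``moKC``    — CLEC4F>=theta_C4 and TIM4<theta_T4 (monocyte-derived KC)
* ``C4negMac``— CLEC4F<theta_C4 (recruited CLEC4F-negative macrophage)

TIM4 status is only evaluated for CLEC4F-positive cells, mirroring the flow
cytometry gate order; a CLEC4F-negative TIM4-positive cell is still a
``C4negMac``.  Ties classify as positive (``>=`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .detection import CellDetection
from .imgio import MultiplexImage

CLASS_LABELS = ("ResKC", "moKC", "C4negMac")

THRESHOLD_MODES = ("fixed", "otsu-on-cell-means", "quantile")


@dataclass
class ClassParams:
    """Marker-positivity thresholds for the CLEC4F/TIM4 gate.

    ``fixed`` uses the given intensity cuts; ``otsu-on-cell-means`` derives
    each cut by Otsu on the distribution of per-cell means (needs >= 3
    cells); ``quantile`` cuts at ``quantile_level`` of the per-cell means.
    """

    threshold_mode: str = "otsu-on-cell-means"
    clec4f_threshold: float | None = None
    tim4_threshold: float | None = None
    quantile_level: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(
                f"threshold_mode must be one of {THRESHOLD_MODES}, "
                f"got {self.threshold_mode!r}"
            )
        if not 0 < self.quantile_level < 1:
            raise ValueError("quantile_level must lie in (0, 1)")
        if self.threshold_mode == "fixed":
            if self.clec4f_threshold is None or self.tim4_threshold is None:
                raise ValueError("fixed mode requires both marker thresholds")
            if self.clec4f_threshold < 0 or self.tim4_threshold < 0:
                raise ValueError("marker thresholds must be >= 0")


def mean_column(channel: str) -> str:
    return f"mean_{channel}"


def extract_features(detections: list[CellDetection], image: MultiplexImage
                     ) -> pd.DataFrame:
    """Per-cell feature table: mean intensity of every channel over each
    detection mask, plus geometry columns.

    The mean is the arithmetic mean of the raw channel intensities over the
    mask pixels and is independent of detection order.
    """
    nrows, ncols = image.shape
    records = []
    channel_names = list(image.channels)
    for det in detections:
        r0, c0 = det.offset
        h, w = det.mask.shape
        if r0 < 0 or c0 < 0 or r0 + h > nrows or c0 + w > ncols:
            raise ValueError(
                f"detection {det.cell_id} lies outside the image geometry "
                f"({nrows}x{ncols})"
            )
        rec = {
            "cell_id": det.cell_id,
            "centroid_row": det.centroid[0],
            "centroid_col": det.centroid[1],
            "area_px": det.area_px,
            "area_um2": det.area_um2,
            "touches_border": det.touches_border,
        }
        for name in channel_names:
            channel = image.channels[name]
            values = channel[r0:r0 + h, c0:c0 + w][det.mask]
            mean = float(values.mean())
            rec[mean_column(name)] = mean
            det.mean_intensities[name] = mean
        records.append(rec)
    columns = [
        "cell_id", "centroid_row", "centroid_col", "area_px", "area_um2",
        "touches_border",
    ] + [mean_column(c) for c in channel_names]
    return pd.DataFrame.from_records(records, columns=columns)


def _resolve_feature_column(features: pd.DataFrame, channel: str) -> str:
    from .imgio import _normalize_channel

    wanted = _normalize_channel(channel)
    for col in features.columns:
        if col.startswith("mean_") and _normalize_channel(col[5:]) == wanted:
            return col
    raise KeyError(
        f"feature table lacks a mean-intensity column for {channel!r}; "
        f"columns: {list(features.columns)}"
    )


def _resolve_threshold(means: np.ndarray, params: ClassParams,
                       fixed_value: float | None) -> float:
    if params.threshold_mode == "fixed":
        return float(fixed_value)
    if fixed_value is not None:  # fixed-value override in any mode
        return float(fixed_value)
    if params.threshold_mode == "quantile":
        return float(np.quantile(means, params.quantile_level))
    if means.size < 3:
        raise ValueError(
            "otsu-on-cell-means needs at least 3 cells; supply fixed "
            "clec4f_threshold/tim4_threshold instead"
        )
    if np.all(means == means[0]):
        # degenerate distribution: everything counts as positive
        return float(means[0])
    return float(threshold_otsu(means))


def classify_cells(features: pd.DataFrame, params: ClassParams) -> pd.DataFrame:
    """Assign exactly one subset label per cell from CLEC4F and TIM4 means.

    Returns a copy of ``features`` with a ``class_label`` column; row order
    and all other columns are preserved.
    """
    out = features.copy()
    if len(out) == 0:
        out["class_label"] = pd.Series(dtype=object)
        return out
    c4_col = _resolve_feature_column(out, "CLEC4F")
    t4_col = _resolve_feature_column(out, "TIM4")
    c4 = out[c4_col].to_numpy(dtype=float)
    t4 = out[t4_col].to_numpy(dtype=float)
    theta_c4 = _resolve_threshold(c4, params, params.clec4f_threshold)
    theta_t4 = _resolve_threshold(t4, params, params.tim4_threshold)

    labels = np.where(
        c4 >= theta_c4,
        np.where(t4 >= theta_t4, "ResKC", "moKC"),
        "C4negMac",
    )
    out["class_label"] = labels
    return out
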