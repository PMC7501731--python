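"""Tiled macrophage detection on the F4/80 channel.

The stage mirrors a tile-based particle-analysis workflow: the image is
processed tile by tile (median filter, threshold), the per-tile binary
results are assembled into one full-size mask, connected components are
labeled globally, holes are filled, and small particles are removed.

Tiles are filtered with a halo of ``median_radius`` pixels of real image
context, so for ``fixed`` and ``global-otsu`` thresholding the result is
bit-identical to processing the whole image at once (tiling invariance).
``per-tile-otsu`` computes one threshold per tile and intentionally breaks
that invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .imgio import MultiplexImage

logger = logging.getLogger(__name__)

THRESHOLD_MODES = ("fixed", "global-otsu", "per-tile-otsu")


@dataclass
class DetectionParams:
    """Parameters of the tiled detection stage.

    Attributes
    ----------
    tile_size
        Edge length of square processing tiles in pixels; must exceed twice
        the median radius.
    tile_overlap
        Extra pixels by which adjacent tiles overlap; overlapping binary
        results are combined by logical OR.
    median_radius
        Radius of the circular median-filter footprint (0 disables).
    threshold_mode
        ``fixed`` uses ``threshold_value``; ``global-otsu`` derives one Otsu
        threshold from the whole filtered image; ``per-tile-otsu`` derives
        one per tile.
    threshold_value
        Intensity cut used in ``fixed`` mode; foreground is ``>= threshold``.
    min_area
        Minimum particle area in pixels; smaller components are removed.
        The default corresponds to ~25 um^2 at a 0.5 um pixel size.
    fill_holes
        Fill holes enclosed by each component before area filtering.
    object_connectivity
        4 or 8; background connectivity for hole filling is the complement.
    """

    tile_size: int = 256
    tile_overlap: int = 0
    median_radius: int = 2
    threshold_mode: str = "global-otsu"
    threshold_value: float | None = None
    min_area: int = 100
    fill_holes: bool = True
    object_connectivity: int = 8

    def __post_init__(self) -> None:
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(
                f"threshold_mode must be one of {THRESHOLD_MODES}, "
                f"got {self.threshold_mode!r}"
            )
        if self.tile_size <= 2 * self.median_radius:
            raise ValueError(
                f"tile_size ({self.tile_size}) must exceed twice the median "
                f"radius ({self.median_radius})"
            )
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.tile_overlap < 0:
            raise ValueError("tile_overlap must be >= 0")
        if self.threshold_mode == "fixed":
            if self.threshold_value is None or self.threshold_value < 0:
                raise ValueError("fixed mode requires threshold_value >= 0")
        if self.object_connectivity not in (4, 8):
            raise ValueError("object_connectivity must be 4 or 8")


@dataclass
class CellDetection:
    """One detected macrophage.

    ``mask`` is the binary mask within the bounding box whose top-left
    corner sits at ``offset`` in full-image coordinates.
    """

    cell_id: int
    mask: np.ndarray
    offset: tuple[int, int]
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    touches_border: bool
    mean_intensities: dict[str, float] = field(default_factory=dict)
    class_label: str | None = None
    zone: str | None = None


def median_filter_channel(channel: np.ndarray, median_radius: int) -> np.ndarray:
    """Median filter with a circular footprint; radius 0 is the identity.

    Edges are handled by reflection.
    """
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    if median_radius == 0:
        return channel.copy()
    footprint = disk(median_radius)
    return ndimage.median_filter(channel, footprint=footprint, mode="reflect")


def _otsu_or_warn(values: np.ndarray) -> float | None:
    """Otsu threshold; returns None (all-background) on a constant image."""
    if np.all(values == values.flat[0]):
        logger.warning("constant image under Otsu thresholding; "
                       "falling back to all-background")
        return None
    return float(threshold_otsu(values))


def threshold_channel(filtered: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Binarize a filtered channel; a pixel is foreground iff its intensity
    is >= the threshold (fixed or Otsu-derived)."""
    if params.threshold_mode == "fixed":
        return filtered >= params.threshold_value
    # global-otsu and per-tile-otsu behave identically on a single array
    thresh = _otsu_or_warn(filtered)
    if thresh is None:
        return np.zeros(filtered.shape, dtype=bool)
    return filtered >= thresh


def _tile_grid(shape: tuple[int, int], tile_size: int, overlap: int
               ) -> Iterator[tuple[int, int, int, int]]:
    """Yield (r0, r1, c0, c1) tile windows covering the image."""
    step = max(tile_size - overlap, 1)
    nrows, ncols = shape
    for r0 in range(0, nrows, step):
        r1 = min(r0 + tile_size, nrows)
        for c0 in range(0, ncols, step):
            c1 = min(c0 + tile_size, ncols)
            yield r0, r1, c0, c1
            if c1 == ncols:
                break
        if r1 == nrows:
            break


def _filtered_full_image(channel: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Assemble the median-filtered image tile by tile.

    Each tile is filtered inside a window expanded by ``median_radius`` of
    real image context, so the assembled result equals filtering the whole
    image at once.
    """
    r = params.median_radius
    if r == 0:
        return channel.astype(channel.dtype, copy=True)
    out = np.empty_like(channel)
    nrows, ncols = channel.shape
    for r0, r1, c0, c1 in _tile_grid(channel.shape, params.tile_size,
                                     params.tile_overlap):
        er0, ec0 = max(r0 - r, 0), max(c0 - r, 0)
        er1, ec1 = min(r1 + r, nrows), min(c1 + r, ncols)
        window = median_filter_channel(channel[er0:er1, ec0:ec1], r)
        out[r0:r1, c0:c1] = window[r0 - er0:r1 - er0, c0 - ec0:c1 - ec0]
    return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def fill_holes(binary: np.ndarray, object_connectivity: int = 8) -> np.ndarray:
    """Fill holes using the complementary background connectivity."""
    background_conn = 4 if object_connectivity == 8 else 8
    structure = _connectivity_structure(background_conn)
    return ndimage.binary_fill_holes(binary, structure=structure)


def detect_macrophages(image: MultiplexImage, params: DetectionParams
                       ) -> list[CellDetection]:
    """Run the full detection stage on the F4/80 channel.

    Per-tile median filter and threshold, assembly into one full-size binary
    mask (overlaps resolved by logical OR), global connected-component
    labeling, hole filling, and minimum-area filtering.  Each surviving
    component yields one :class:`CellDetection`; masks are pairwise disjoint.
    """
    if not image.has_channel("F4/80"):
        raise KeyError(
            "image lacks the F4/80 detection channel; available: "
            f"{sorted(image.channels)}"
        )
    channel = np.asarray(image.get_channel("F4/80"), dtype=float)
    filtered = _filtered_full_image(channel, params)

    if params.threshold_mode == "per-tile-otsu":
        binary = np.zeros(channel.shape, dtype=bool)
        for r0, r1, c0, c1 in _tile_grid(channel.shape, params.tile_size,
                                         params.tile_overlap):
            tile = filtered[r0:r1, c0:c1]
            thresh = _otsu_or_warn(tile)
            if thresh is not None:
                binary[r0:r1, c0:c1] |= tile >= thresh
    else:
        binary = threshold_channel(filtered, params)

    if params.fill_holes:
        binary = fill_holes(binary, params.object_connectivity)

    structure = _connectivity_structure(params.object_connectivity)
    labels, n = ndimage.label(binary, structure=structure)
    detections: list[CellDetection] = []
    if n == 0:
        return detections
    slices = ndimage.find_objects(labels)
    nrows, ncols = channel.shape
    cell_id = 0
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        area = int(mask.sum())
        if area < params.min_area:
            continue
        cell_id += 1
        rows, cols = np.nonzero(mask)
        r0, c0 = sl[0].start, sl[1].start
        centroid = (float(rows.mean() + r0), float(cols.mean() + c0))
        touches = (
            r0 == 0 or c0 == 0
            or sl[0].stop == nrows or sl[1].stop == ncols
        )
        detections.append(CellDetection(
            cell_id=cell_id,
            mask=mask,
            offset=(r0, c0),
            centroid=centroid,
            area_px=area,
            area_um2=area * image.pixel_size ** 2,
            touches_border=touches,
        ))
    return detections


def detections_to_label_image(detections: list[CellDetection],
                              shape: tuple[int, int]) -> np.ndarray:
    """Render detections as a label image (pixel value = cell_id)."""
    labels = np.zeros(shape, dtype=np.int32)
    for det in detections:
        r0, c0 = det.offset
        h, w = det.mask.shape
        region = labels[r0:r0 + h, c0:c0 + w]
        region[det.mask] = det.cell_id
    return labels
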