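"""Reading and writing of every artifact the pipeline touches.

Images travel as multi-page TIFF (one page per channel, channel name stored
in each page's description), annotations as GeoJSON FeatureCollections,
tables as CSV, configuration as plain-text YAML key-value files.

Coordinates are 0-based ``(row, col)`` internally.  GeoJSON export uses
``(x=col, y=row)`` with y increasing downward, matching digital-pathology
viewers, and treats each pixel as the unit square centred on its integer
coordinate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon, box, mapping, shape as shapely_shape
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

#: Canonical channel names used throughout the pipeline.
CANONICAL_CHANNELS = ("F4/80", "CLEC4F", "TIM4", "Desmin", "CD31")


def _normalize_channel(name: str) -> str:
    """Collapse case, separators and the F4/80 spelling variants."""
    squashed = name.strip().upper().replace("-", "").replace("_", "")
    squashed = squashed.replace("/", "").replace(" ", "")
    return squashed


_ALIAS_TABLE = {_normalize_channel(c): c for c in CANONICAL_CHANNELS}


@dataclass
class MultiplexImage:
    """Named 2D intensity channels sharing geometry and physical pixel size.

    Parameters
    ----------
    channels
        Mapping channel name -> 2D non-negative intensity array. All arrays
        must share one shape.
    pixel_size
        Physical pixel size in micrometres per pixel; must be positive.
    image_id
        Free-form identifier carried into every downstream table.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    image_id: str = "image"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def resolve_channel(self, name: str) -> str:
        """Return the stored key matching ``name`` case/alias-insensitively."""
        if name in self.channels:
            return name
        wanted = _normalize_channel(name)
        for stored in self.channels:
            if _normalize_channel(stored) == wanted:
                return stored
        raise KeyError(
            f"channel {name!r} not found; available channels: "
            f"{sorted(self.channels)}"
        )

    def get_channel(self, name: str) -> np.ndarray:
        return self.channels[self.resolve_channel(name)]

    def has_channel(self, name: str) -> bool:
        try:
            self.resolve_channel(name)
            return True
        except KeyError:
            return False


@dataclass
class AnnotationSet:
    """Cell outlines as simple polygons in pixel coordinates.

    Each entry is ``(cell_id, class_label, vertices)`` with vertices as an
    ``(n, 2)`` array of ``(row, col)`` pixel coordinates.
    """

    polygons: list[tuple[int, str, np.ndarray]] = field(default_factory=list)
    image_id: str = "image"


# ---------------------------------------------------------------------------
# multi-channel TIFF
# ---------------------------------------------------------------------------

def write_multichannel_tiff(image: MultiplexImage, path: str | Path) -> None:
    """Write one TIFF page per channel; the page description carries the
    channel name, pixel size and image id as a small JSON object."""
    path = Path(path)
    with tifffile.TiffWriter(path) as writer:
        for name, arr in image.channels.items():
            meta = {
                "channel": name,
                "pixel_size_um": image.pixel_size,
                "image_id": image.image_id,
            }
            writer.write(arr, description=json.dumps(meta))


def read_multichannel_tiff(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_size: float | None = None,
    image_id: str | None = None,
) -> MultiplexImage:
    """Read a multi-page TIFF into a :class:`MultiplexImage`.

    Channel names come from per-page metadata when present, otherwise from
    ``channel_names`` in page order.  Integer data round-trips losslessly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    channels: dict[str, np.ndarray] = {}
    meta_pixel_size = None
    meta_image_id = None
    with tifffile.TiffFile(path) as tf:
        pages = list(tf.pages)
        if channel_names is not None and len(pages) < len(channel_names):
            raise ValueError(
                f"{path} has {len(pages)} pages but {len(channel_names)} "
                "channels were requested"
            )
        for i, page in enumerate(pages):
            arr = page.asarray()
            name = None
            desc = page.description or ""
            if desc:
                try:
                    meta = json.loads(desc)
                    name = meta.get("channel")
                    meta_pixel_size = meta.get("pixel_size_um", meta_pixel_size)
                    meta_image_id = meta.get("image_id", meta_image_id)
                except (json.JSONDecodeError, AttributeError):
                    name = desc.strip() or None
            if name is None and channel_names is not None and i < len(channel_names):
                name = channel_names[i]
            if name is None:
                name = f"channel_{i}"
            channels[name] = arr
    image = MultiplexImage(
        channels=channels,
        pixel_size=pixel_size or meta_pixel_size or 1.0,
        image_id=image_id or meta_image_id or path.stem,
    )
    if channel_names is not None:
        for requested in channel_names:
            image.resolve_channel(requested)  # raises listing available names
    return image


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label image (pixel value = object/zone id)."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.int32))


def read_label_tiff(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label image not found: {path}")
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# GeoJSON annotations
# ---------------------------------------------------------------------------

def mask_to_polygon(mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> Polygon | None:
    """Trace the outer boundary of a binary mask as a polygon.

    The polygon is the boundary of the union of unit squares centred on the
    foreground pixels, so its shoelace area equals the pixel count exactly.
    Holes are dropped (they are filled upstream).  Returns ``None`` for an
    empty mask.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    r0, c0 = offset
    squares = [
        box(c + c0 - 0.5, r + r0 - 0.5, c + c0 + 0.5, r + r0 + 0.5)
        for r, c in zip(rows.tolist(), cols.tolist())
    ]
    merged = unary_union(squares)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return Polygon(merged.exterior)


def export_annotations(detections, image_id: str) -> dict:
    """Serialize detections as a GeoJSON FeatureCollection.

    One polygon per detection (outer boundary of its mask); the class label,
    cell id and centroid are stored as feature properties.  Detections with
    empty masks are skipped with a logged warning.
    """
    features = []
    for det in detections:
        poly = mask_to_polygon(det.mask, det.offset)
        if poly is None:
            logger.warning("detection %s has an empty mask; skipped", det.cell_id)
            continue
        props = {
            "cell_id": det.cell_id,
            "class_label": det.class_label,
            "centroid_row": float(det.centroid[0]),
            "centroid_col": float(det.centroid[1]),
            "area_px": int(det.area_px),
        }
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"image_id": image_id},
    }


def write_annotations(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Parse a GeoJSON FeatureCollection back into an :class:`AnnotationSet`."""
    data = json.loads(Path(path).read_text())
    polygons = []
    for feat in data.get("features", []):
        geom = shapely_shape(feat["geometry"])
        props = feat.get("properties", {})
        xy = np.asarray(geom.exterior.coords)
        vertices = np.column_stack([xy[:, 1], xy[:, 0]])  # (row, col)
        polygons.append(
            (props.get("cell_id", -1), props.get("class_label"), vertices)
        )
    image_id = data.get("properties", {}).get("image_id", "image")
    return AnnotationSet(polygons=polygons, image_id=image_id)


# ---------------------------------------------------------------------------
# tables and configuration
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)


def save_config(config: dict, path: str | Path) -> None:
    """Serialize a configuration as a plain-text key-value (YAML) file."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    return yaml.safe_load(path.read_text()) or {}
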