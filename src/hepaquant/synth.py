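"""Synthetic multiplex tissue images and droplet probability stacks.

Everything downstream is testable against exact ground truth generated
here.  The tissue generator emulates the geometry the quantification
pipeline was designed for: blob-like macrophages whose marker intensities
follow the subset logic (ResKC F4/80+CLEC4F+TIM4+, moKC F4/80+CLEC4F+TIM4-,
CLEC4F- mac F4/80+CLEC4F-), Desmin-high patches in which CLEC4F- macs are
enriched by a configurable density ratio, vessel rings co-high for Desmin
and CD31 with a signal-free lumen, additive Gaussian noise.  The droplet
generator produces Gaussian-blurred spheres rescaled to peak probability 1,
with known lattice volumes, plus optional adversarial compact components of
exact voxel counts.

All randomness flows through one integer-seeded generator per call, so an
identical spec yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imgio import CANONICAL_CHANNELS, MultiplexImage
from .zoning import LABEL_EXCLUDED, LABEL_HI, LABEL_LO, ZoneMap

TISSUE_CLASSES = ("ResKC", "moKC", "C4negMac", "distractor")

#: Default absolute foreground intensity per class and channel (a.u.).
#: Entries at or below the channel background mean "not expressed".
DEFAULT_INTENSITY_MATRIX = {
    "ResKC": {"F4/80": 200.0, "CLEC4F": 200.0, "TIM4": 200.0},
    "moKC": {"F4/80": 200.0, "CLEC4F": 200.0, "TIM4": 0.0},
    "C4negMac": {"F4/80": 200.0, "CLEC4F": 0.0, "TIM4": 0.0},
    "distractor": {"F4/80": 0.0, "CLEC4F": 0.0, "TIM4": 150.0},
}


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested objects."""


@dataclass
class TissueSpec:
    """Recipe for one synthetic multiplex tissue image.

    ``enrichment_rho`` is the ratio of CLEC4F- mac placement density in
    Desmin-high versus Desmin-low regions (1 = uniform, >1 = enriched in
    high-Desmin patches, 0 = never in them).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5  # um / pixel
    n_cells_per_class: dict[str, int] = field(default_factory=lambda: {
        "ResKC": 60, "moKC": 25, "C4negMac": 15, "distractor": 10})
    cell_radius: tuple[float, float] = (10.0, 1.0)  # mean, sd in pixels
    intensity_matrix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in
                                 DEFAULT_INTENSITY_MATRIX.items()})
    background_level: dict[str, float] | float = 10.0
    noise_sd: float = 5.0
    n_hi_patches: int = 3
    hi_patch_radius: float = 60.0
    enrichment_rho: float = 4.0
    desmin_hi_gain: float = 3.0
    n_vessels: int = 2
    vessel_radius: float = 25.0
    vessel_intensity: float = 200.0
    allow_overlap: bool = False
    min_cell_gap: float = 6.0  # pixels between cell boundaries
    seed: int = 0
    image_id: str = "synthetic"
    max_attempts_per_cell: int = 2000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for cls, n in self.n_cells_per_class.items():
            if cls not in TISSUE_CLASSES:
                raise ValueError(f"unknown cell class {cls!r}")
            if n < 0:
                raise ValueError("cell counts must be >= 0")
        if self.cell_radius[0] <= 0 or self.cell_radius[1] < 0:
            raise ValueError("cell radius mean must be > 0, sd >= 0")
        if self.enrichment_rho < 0:
            raise ValueError("enrichment_rho must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hi_patch_radius <= 0 or self.vessel_radius <= 0:
            raise ValueError("radii must be > 0")
        fg = self.intensity_matrix.get("distractor", {}).get("F4/80", 0.0)
        if fg > self._background("F4/80"):
            raise ValueError("distractor must keep F4/80 at background")

    def _background(self, channel: str) -> float:
        if isinstance(self.background_level, dict):
            return float(self.background_level.get(channel, 0.0))
        return float(self.background_level)


@dataclass
class CellTruth:
    """Ground truth for one planted cell."""

    cell_id: int
    class_label: str
    centroid: tuple[int, int]
    radius: float
    zone: str


def _disk_coords(center: tuple[int, int], radius: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Lattice points of the digital disk (row-r)^2+(col-c)^2 <= radius^2."""
    r0, c0 = center
    n = int(math.floor(radius))
    rr, cc = np.mgrid[-n:n + 1, -n:n + 1]
    inside = rr * rr + cc * cc <= radius * radius
    rows = rr[inside] + r0
    cols = cc[inside] + c0
    keep = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[keep], cols[keep]


_ZONE_NAME = {LABEL_EXCLUDED: "excluded", LABEL_LO: "Lo", LABEL_HI: "Hi"}


def generate_tissue_image(spec: TissueSpec
                          ) -> tuple[MultiplexImage, list[CellTruth],
                                     ZoneMap, np.ndarray]:
    """Generate one tissue image with exact cell, zone and vessel truth.

    Returns the image, one :class:`CellTruth` per planted cell, the true
    zone map (vessel disks excluded, patches Desmin-high, rest Desmin-low)
    and the boolean vessel mask (full vessel disks, ring plus lumen).

    Cells are hard disks placed by rejection sampling; a spec too dense to
    satisfy raises :class:`PlacementError` naming the achievable count.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    nrows, ncols = shape

    # --- Desmin-high patches ------------------------------------------------
    hi_mask = np.zeros(shape, dtype=bool)
    pr = spec.hi_patch_radius
    for _ in range(spec.n_hi_patches):
        center = (int(rng.integers(0, nrows)), int(rng.integers(0, ncols)))
        rows, cols = _disk_coords(center, pr, shape)
        hi_mask[rows, cols] = True

    # --- vessels (annuli; lumen signal-free; mask = full disk) --------------
    vessel_mask = np.zeros(shape, dtype=bool)
    ring_mask = np.zeros(shape, dtype=bool)
    vr = spec.vessel_radius
    vessel_centers: list[tuple[int, int]] = []
    margin = int(math.ceil(vr)) + 1
    attempts = 0
    while len(vessel_centers) < spec.n_vessels:
        attempts += 1
        if attempts > spec.max_attempts_per_cell * max(spec.n_vessels, 1):
            raise PlacementError(
                f"could not place {spec.n_vessels} vessels; achievable with "
                f"this geometry: {len(vessel_centers)}")
        if nrows <= 2 * margin or ncols <= 2 * margin:
            raise PlacementError("image too small for the requested vessels")
        cand = (int(rng.integers(margin, nrows - margin)),
                int(rng.integers(margin, ncols - margin)))
        if any((cand[0] - v[0]) ** 2 + (cand[1] - v[1]) ** 2
               <= (2 * vr + 2) ** 2 for v in vessel_centers):
            continue
        vessel_centers.append(cand)
        rows, cols = _disk_coords(cand, vr, shape)
        vessel_mask[rows, cols] = True
        rr, cc = _disk_coords(cand, 0.6 * vr, shape)
        lumen = np.zeros(shape, dtype=bool)
        lumen[rr, cc] = True
        disk_full = np.zeros(shape, dtype=bool)
        disk_full[rows, cols] = True
        ring_mask |= disk_full & ~lumen

    # --- zone truth ---------------------------------------------------------
    zone_labels = np.full(shape, LABEL_LO, dtype=np.uint8)
    zone_labels[hi_mask] = LABEL_HI
    zone_labels[vessel_mask] = LABEL_EXCLUDED
    zone_truth = ZoneMap(labels=zone_labels, pixel_size=spec.pixel_size)

    # --- cells --------------------------------------------------------------
    rho = spec.enrichment_rho
    p_hi = 1.0 if rho >= 1 else rho
    p_lo = (1.0 / rho) if rho >= 1 else 1.0
    if rho == 0:
        p_hi, p_lo = 0.0, 1.0

    placed: list[tuple[int, int, float]] = []  # row, col, radius
    truths: list[CellTruth] = []
    cell_id = 0
    for cls in TISSUE_CLASSES:
        n_wanted = spec.n_cells_per_class.get(cls, 0)
        for _ in range(n_wanted):
            radius = max(1.0, float(rng.normal(*spec.cell_radius)))
            m = int(math.ceil(radius)) + 1
            if nrows <= 2 * m or ncols <= 2 * m:
                raise PlacementError("image too small for the requested cells")
            for attempt in range(spec.max_attempts_per_cell):
                cand = (int(rng.integers(m, nrows - m)),
                        int(rng.integers(m, ncols - m)))
                # keep out of vessels
                if any((cand[0] - v[0]) ** 2 + (cand[1] - v[1]) ** 2
                       <= (vr + radius + 1) ** 2 for v in vessel_centers):
                    continue
                # gap of a few pixels so smoothing cannot bridge neighbours
                if not spec.allow_overlap and any(
                        (cand[0] - r) ** 2 + (cand[1] - c) ** 2
                        <= (radius + rad + spec.min_cell_gap) ** 2
                        for r, c, rad in placed):
                    continue
                if cls == "C4negMac":
                    in_hi = bool(hi_mask[cand])
                    accept_p = p_hi if in_hi else p_lo
                    if rng.random() >= accept_p:
                        continue
                placed.append((cand[0], cand[1], radius))
                cell_id += 1
                truths.append(CellTruth(
                    cell_id=cell_id,
                    class_label=cls,
                    centroid=cand,
                    radius=radius,
                    zone=_ZONE_NAME[int(zone_labels[cand])],
                ))
                break
            else:
                raise PlacementError(
                    f"could not place cell {len(placed) + 1} of class {cls}; "
                    f"achievable density with this geometry: {len(placed)} "
                    "cells")

    # --- render channels ----------------------------------------------------
    channels: dict[str, np.ndarray] = {}
    for ch in CANONICAL_CHANNELS:
        channels[ch] = np.full(shape, spec._background(ch), dtype=float)

    for truth in truths:
        row_int = spec.intensity_matrix.get(truth.class_label, {})
        rows, cols = _disk_coords(truth.centroid, truth.radius, shape)
        for ch, value in row_int.items():
            if value > spec._background(ch):
                channels[ch][rows, cols] = value

    # Desmin elevated in high patches (multiplicative) and on vessel rings;
    # CD31 high on vessel rings only.
    channels["Desmin"][hi_mask] *= spec.desmin_hi_gain
    channels["Desmin"][ring_mask] = np.maximum(
        channels["Desmin"][ring_mask], spec.vessel_intensity)
    channels["CD31"][ring_mask] = np.maximum(
        channels["CD31"][ring_mask], spec.vessel_intensity)

    if spec.noise_sd > 0:
        for ch in CANONICAL_CHANNELS:
            channels[ch] += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(channels[ch], 0.0, None, out=channels[ch])

    image = MultiplexImage(channels=channels, pixel_size=spec.pixel_size,
                           image_id=spec.image_id)
    return image, truths, zone_truth, vessel_mask


def truth_table(truths: list[CellTruth]) -> pd.DataFrame:
    """Cell truth as a DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "cell_id": t.cell_id,
        "class_label": t.class_label,
        "centroid_row": t.centroid[0],
        "centroid_col": t.centroid[1],
        "radius": t.radius,
        "zone": t.zone,
    } for t in truths], columns=["cell_id", "class_label", "centroid_row",
                                 "centroid_col", "radius", "zone"])


# ---------------------------------------------------------------------------
# 3D droplet stacks
# ---------------------------------------------------------------------------

@dataclass
class DropletSpec:
    """Recipe for one synthetic droplet probability stack.

    ``adversarial_components`` plants compact binary components with the
    exact voxel counts given, pairwise separated by ``min_separation``
    voxels (default 8, i.e. more than twice the default opening radius
    plus one) from each other and from every droplet.
    """

    stack_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: tuple[float, float, float] = (5.0, 5.0, 5.0)  # nm (z, y, x)
    n_droplets: int = 8
    radius_distribution: tuple[float, float] = (10.0, 1.5)  # mean, sd voxels
    blur_sigma: float = 1.0
    noise_sd: float = 0.02
    adversarial_components: list[int] | None = None
    min_separation: int = 8
    seed: int = 0
    max_attempts_per_droplet: int = 2000

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stack_shape):
            raise ValueError("stack_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        if self.radius_distribution[0] <= 0 or self.radius_distribution[1] < 0:
            raise ValueError("radius mean must be > 0, sd >= 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        if self.adversarial_components is not None:
            if any(n < 1 for n in self.adversarial_components):
                raise ValueError("adversarial component counts must be >= 1")


def digital_ball_coords(center: tuple[int, int, int], radius: float,
                        shape: tuple[int, int, int]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lattice points of the digital ball ||v - center|| <= radius."""
    z0, y0, x0 = center
    n = int(math.floor(radius))
    zz, yy, xx = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
    inside = zz * zz + yy * yy + xx * xx <= radius * radius
    z = zz[inside] + z0
    y = yy[inside] + y0
    x = xx[inside] + x0
    keep = ((z >= 0) & (z < shape[0]) & (y >= 0) & (y < shape[1])
            & (x >= 0) & (x < shape[2]))
    return z[keep], y[keep], x[keep]


def _compact_block_coords(n_voxels: int, origin: tuple[int, int, int]
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First ``n_voxels`` lattice points of a near-cubic box in scan order.

    A scan-order prefix of a box is always 6-connected, so the block is a
    single compact component of exactly ``n_voxels`` voxels.
    """
    a = max(1, int(math.ceil(n_voxels ** (1.0 / 3.0))))
    while a ** 3 < n_voxels:
        a += 1
    idx = np.arange(n_voxels)
    z = idx // (a * a)
    rem = idx % (a * a)
    y = rem // a
    x = rem % a
    return z + origin[0], y + origin[1], x + origin[2]


def _block_extent(n_voxels: int) -> int:
    a = max(1, int(math.ceil(n_voxels ** (1.0 / 3.0))))
    while a ** 3 < n_voxels:
        a += 1
    return a


def generate_droplet_stack(spec: DropletSpec
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a droplet probability stack with exact volume truth.

    Returns the float stack (values in [0, 1]) and a truth table with one
    row per planted object: ``droplet_id``, ``kind`` (droplet/adversarial),
    center, radius (NaN for adversarial blocks) and exact lattice voxel
    count.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.stack_shape)
    binary = np.zeros(shape, dtype=bool)
    records = []

    # adversarial compact blocks first, at deterministic positions
    adv_coords = []
    if spec.adversarial_components:
        cursor = 1
        for i, n_vox in enumerate(spec.adversarial_components):
            a = _block_extent(n_vox)
            if cursor + a + 1 > shape[2] or a + 2 > shape[1] or a + 2 > shape[0]:
                raise PlacementError(
                    f"adversarial component of {n_vox} voxels does not fit "
                    f"in stack of shape {shape}")
            z, y, x = _compact_block_coords(n_vox, (1, 1, cursor))
            adv_coords.append((np.c_[z, y, x], a, (1, 1, cursor)))
            records.append({
                "droplet_id": -(i + 1), "kind": "adversarial",
                "center_z": 1, "center_y": 1, "center_x": cursor,
                "radius": np.nan, "voxels": int(n_vox),
            })
            cursor += a + spec.min_separation

    placed: list[tuple[tuple[int, int, int], float]] = []
    for i in range(spec.n_droplets):
        radius = max(2.0, float(rng.normal(*spec.radius_distribution)))
        m = int(math.ceil(radius)) + 2
        if any(2 * m >= s for s in shape):
            raise PlacementError(
                f"droplet of radius {radius:.1f} does not fit in stack of "
                f"shape {shape}")
        for attempt in range(spec.max_attempts_per_droplet):
            cand = tuple(int(rng.integers(m, s - m)) for s in shape)
            if any(sum((a - b) ** 2 for a, b in zip(cand, c))
                   <= (radius + r + spec.min_separation) ** 2
                   for c, r in placed):
                continue
            # keep clear of adversarial blocks
            ok = True
            for coords, a, origin in adv_coords:
                lo = np.array(origin) - (radius + spec.min_separation)
                hi = np.array(origin) + a + (radius + spec.min_separation)
                if all(lo[d] <= cand[d] <= hi[d] for d in range(3)):
                    ok = False
                    break
            if not ok:
                continue
            placed.append((cand, radius))
            z, y, x = digital_ball_coords(cand, radius, shape)
            binary[z, y, x] = True
            records.append({
                "droplet_id": i + 1, "kind": "droplet",
                "center_z": cand[0], "center_y": cand[1], "center_x": cand[2],
                "radius": radius, "voxels": int(z.size),
            })
            break
        else:
            raise PlacementError(
                f"could not place droplet {i + 1} without overlap; "
                f"achievable: {len(placed)} droplets in shape {shape}")

    stack = binary.astype(float)
    if spec.blur_sigma > 0 and stack.any():
        stack = gaussian_filter(stack, sigma=spec.blur_sigma)
        stack /= stack.max()  # rescale to peak probability 1

    # plant adversarial blocks as exact binary components, after blurring
    for coords, _, _ in adv_coords:
        stack[coords[:, 0], coords[:, 1], coords[:, 2]] = 1.0

    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=shape)
    stack = np.clip(stack, 0.0, 1.0)

    truth = pd.DataFrame(records, columns=[
        "droplet_id", "kind", "center_z", "center_y", "center_x",
        "radius", "voxels"])
    return stack, truth
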