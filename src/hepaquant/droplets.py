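"""Lipid-droplet post-processing and volumetry for FIB-SEM probability maps.

The pipeline consumes a 3D probability map (voxel values in [0, 1], e.g.
the output of a trained segmentation network) and applies, in order:

1. probability threshold (foreground iff p >= threshold),
2. removal of connected components smaller than ``min_voxels`` (default 27,
   i.e. anything smaller than a 3x3x3 block is treated as noise),
3. morphological opening with a spherical structuring element (digital
   Euclidean ball, default radius 2 voxels),

then labels the surviving droplets and reports per-component and total
volumes in voxels and cubic micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CONNECTIVITY_STRUCTURES = {6: 1, 18: 2, 26: 3}


def digital_ball(radius: float, voxel_size: tuple[float, float, float] | None = None
                 ) -> np.ndarray:
    """Digital Euclidean ball: lattice points within distance ``radius``.

    With ``voxel_size`` the distance is measured in physical units
    (anisotropic ball); the radius is then in multiples of the smallest
    voxel dimension.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if voxel_size is None:
        n = int(np.floor(radius))
        z, y, x = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
        return (z * z + y * y + x * x) <= radius * radius
    vz, vy, vx = voxel_size
    unit = min(voxel_size)
    r_phys = radius * unit
    nz = int(np.floor(r_phys / vz))
    ny = int(np.floor(r_phys / vy))
    nx = int(np.floor(r_phys / vx))
    z, y, x = np.mgrid[-nz:nz + 1, -ny:ny + 1, -nx:nx + 1]
    return ((z * vz) ** 2 + (y * vy) ** 2 + (x * vx) ** 2) <= r_phys ** 2


@dataclass
class DropletParams:
    """Post-processing parameters.

    ``voxel_size`` is (z, y, x) in nanometres; the z step matches the 5 nm
    FIB milling sections, the lateral size defaults to the same for an
    isotropic voxel.  ``anisotropic_element`` switches the structuring
    element from a voxel-unit ball to a physical-unit ball.
    """

    prob_threshold: float = 0.5
    min_voxels: int = 27
    opening_radius: int = 2
    connectivity_3d: int = 26
    voxel_size: tuple[float, float, float] = (5.0, 5.0, 5.0)
    anisotropic_element: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.prob_threshold <= 1:
            raise ValueError("prob_threshold must lie in [0, 1]")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.connectivity_3d not in CONNECTIVITY_STRUCTURES:
            raise ValueError("connectivity_3d must be 6, 18 or 26")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")


@dataclass
class DropletResult:
    """Labeled droplet volume with per-component and total volumes."""

    labels: np.ndarray
    voxel_counts: list[int]
    total_volume_voxels: int
    total_volume_um3: float
    n_components: int
    params: DropletParams = field(repr=False, default=None)


def threshold_probability(stack: np.ndarray, prob_threshold: float) -> np.ndarray:
    """Binarize a probability map; a voxel is foreground iff p >= threshold."""
    stack = np.asarray(stack)
    if stack.size and (stack.min() < 0 or stack.max() > 1):
        raise ValueError(
            f"probability values must lie in [0, 1]; found range "
            f"[{stack.min()}, {stack.max()}]"
        )
    return stack >= prob_threshold


def _structure(connectivity_3d: int) -> np.ndarray:
    return ndimage.generate_binary_structure(
        3, CONNECTIVITY_STRUCTURES[connectivity_3d])


def remove_small_components(binary: np.ndarray, min_voxels: int,
                            connectivity_3d: int = 26) -> np.ndarray:
    """Drop connected components with fewer than ``min_voxels`` voxels."""
    labels, n = ndimage.label(binary, structure=_structure(connectivity_3d))
    if n == 0:
        return binary.astype(bool).copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def spherical_opening(binary: np.ndarray, opening_radius: int,
                      voxel_size: tuple[float, float, float] | None = None
                      ) -> np.ndarray:
    """Morphological opening by a digital Euclidean ball.

    Erosion then dilation with the same element; voxels outside the volume
    count as background, so the result is always a subset of the input.
    """
    binary = np.asarray(binary).astype(bool)
    if opening_radius == 0:
        return binary.copy()
    element = digital_ball(opening_radius, voxel_size)
    eroded = ndimage.binary_erosion(binary, structure=element, border_value=0)
    return ndimage.binary_dilation(eroded, structure=element, border_value=0)


def run_droplet_pipeline(stack: np.ndarray, params: DropletParams) -> DropletResult:
    """Threshold, denoise, open, and measure droplet volumes.

    Stages run in that fixed order; volumes are reported in voxels and in
    cubic micrometres using the (possibly anisotropic) voxel size.
    """
    binary = threshold_probability(stack, params.prob_threshold)
    binary = remove_small_components(binary, params.min_voxels,
                                     params.connectivity_3d)
    binary = spherical_opening(
        binary, params.opening_radius,
        params.voxel_size if params.anisotropic_element else None)
    labels, n = ndimage.label(binary, structure=_structure(params.connectivity_3d))
    counts = (np.bincount(labels.ravel())[1:].tolist() if n else [])
    total_vox = int(sum(counts))
    vz, vy, vx = params.voxel_size  # nm
    voxel_um3 = (vz * vy * vx) * 1e-9
    return DropletResult(
        labels=labels,
        voxel_counts=[int(c) for c in counts],
        total_volume_voxels=total_vox,
        total_volume_um3=total_vox * voxel_um3,
        n_components=int(n),
        params=params,
    )
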