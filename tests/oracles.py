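"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the mathematical definition (window
medians, exhaustive threshold search, BFS flood fill, set-definition
erosion/dilation, lattice enumeration) and never calls the library code
paths it is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


# --- 2D -----------------------------------------------------------------

def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius]


def brute_force_median(image: np.ndarray, radius: int) -> np.ndarray:
    """Exhaustive window median with a circular footprint, reflect edges."""
    padded = np.pad(image, radius, mode="symmetric")  # edge-repeating reflection
    out = np.empty_like(image)
    offs = disk_offsets(radius)
    nrows, ncols = image.shape
    for r in range(nrows):
        for c in range(ncols):
            window = [padded[r + radius + dr, c + radius + dc]
                      for dr, dc in offs]
            out[r, c] = np.median(window)
    return out


def exhaustive_otsu(values: np.ndarray) -> float:
    """Threshold minimizing weighted intra-class variance, searched over
    midpoints between consecutive distinct values."""
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(vals)
    assert uniq.size >= 2
    best_t, best_score = None, np.inf
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        below = vals[vals < t]
        above = vals[vals >= t]
        score = below.size * below.var() + above.size * above.var()
        if score < best_score:
            best_score, best_t = score, t
    return best_t


def lattice_disk_count(radius: float) -> int:
    """Number of lattice points with x^2 + y^2 <= r^2."""
    n = int(np.floor(radius))
    return sum(1 for x in range(-n, n + 1) for y in range(-n, n + 1)
               if x * x + y * y <= radius * radius)


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# --- 3D -----------------------------------------------------------------

def lattice_ball_count(radius: float) -> int:
    n = int(np.floor(radius))
    return sum(1 for x in range(-n, n + 1) for y in range(-n, n + 1)
               for z in range(-n, n + 1)
               if x * x + y * y + z * z <= radius * radius)


def ball_offsets(radius: float) -> list[tuple[int, int, int]]:
    n = int(np.floor(radius))
    return [(z, y, x)
            for z in range(-n, n + 1)
            for y in range(-n, n + 1)
            for x in range(-n, n + 1)
            if z * z + y * y + x * x <= radius * radius]


def neighbor_offsets_3d(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_label(volume: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """BFS connected-component labeling; labels assigned in scan order."""
    volume = np.asarray(volume).astype(bool)
    labels = np.zeros(volume.shape, dtype=np.int32)
    offs = neighbor_offsets_3d(connectivity)
    nz, ny, nx = volume.shape
    next_label = 0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not volume[z0, y0, x0] or labels[z0, y0, x0]:
                    continue
                next_label += 1
                queue = deque([(z0, y0, x0)])
                labels[z0, y0, x0] = next_label
                while queue:
                    z, y, x = queue.popleft()
                    for dz, dy, dx in offs:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                and volume[zz, yy, xx]
                                and not labels[zz, yy, xx]):
                            labels[zz, yy, xx] = next_label
                            queue.append((zz, yy, xx))
    return labels


def remove_small_bruteforce(volume: np.ndarray, min_voxels: int,
                            connectivity: int = 26) -> np.ndarray:
    labels = flood_fill_label(volume, connectivity)
    out = np.zeros(volume.shape, dtype=bool)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= min_voxels:
            out |= comp
    return out


def erode_bruteforce(volume: np.ndarray, offsets) -> np.ndarray:
    """Set-definition erosion: x survives iff x+b is foreground for every
    offset b; points outside the volume count as background."""
    volume = np.asarray(volume).astype(bool)
    nz, ny, nx = volume.shape
    out = np.zeros_like(volume)
    fg = np.argwhere(volume)
    for z, y, x in fg:
        ok = True
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                    and volume[zz, yy, xx]):
                ok = False
                break
        out[z, y, x] = ok
    return out


def dilate_bruteforce(volume: np.ndarray, offsets) -> np.ndarray:
    """Set-definition dilation: union of translates of the element over
    every foreground point (clipped at the volume boundary)."""
    volume = np.asarray(volume).astype(bool)
    nz, ny, nx = volume.shape
    out = np.zeros_like(volume)
    for z, y, x in np.argwhere(volume):
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                out[zz, yy, xx] = True
    return out


def opening_bruteforce(volume: np.ndarray, radius: float) -> np.ndarray:
    offs = ball_offsets(radius)
    return dilate_bruteforce(erode_bruteforce(volume, offs), offs)


def droplet_pipeline_bruteforce(stack: np.ndarray, prob_threshold: float,
                                min_voxels: int, opening_radius: float,
                                connectivity: int = 26) -> np.ndarray:
    """Full reference pipeline: threshold, flood-fill size filter,
    set-definition opening.  Returns the final binary volume."""
    binary = np.asarray(stack) >= prob_threshold
    binary = remove_small_bruteforce(binary, min_voxels, connectivity)
    if opening_radius > 0:
        binary = opening_bruteforce(binary, opening_radius)
    return binary
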