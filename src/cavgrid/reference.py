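"""Slow, direct reference implementations for validation.

Every routine here recomputes a quantity of the main pipeline by the most
literal method available — direct convolution, exhaustive per-voxel line
walks, breadth-first flood fill, threshold-and-search percolation — sharing
no code with the production implementations they are checked against. They
are exponentially simpler and correspondingly slower; use them only on small
grids.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .gridcore import LabelField
from .pockets import PocketParams, SCAN_DIRECTIONS

__all__ = [
    "naive_gaussian_blur",
    "naive_dog",
    "naive_psp",
    "flood_fill_components",
    "naive_local_bottleneck",
]


def _gauss_kernel_1d(sigma: float) -> np.ndarray:
    """Discrete normalized Gaussian, truncated at 4 sigma (matching the
    convention of standard image-filtering libraries)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def naive_gaussian_blur(values: np.ndarray, sigma_voxels: float) -> np.ndarray:
    """Direct (non-separated) 3D Gaussian convolution with edge padding."""
    k1 = _gauss_kernel_1d(sigma_voxels)
    r = (len(k1) - 1) // 2
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    padded = np.pad(values.astype(float), r, mode="edge")
    out = np.empty_like(values, dtype=float)
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                block = padded[i : i + 2 * r + 1, j : j + 2 * r + 1, k : k + 2 * r + 1]
                out[i, j, k] = float((block * kernel).sum())
    return out


def naive_dog(labels: LabelField, params: PocketParams) -> np.ndarray:
    """Difference of two direct Gaussian convolutions of the solvent indicator."""
    s = labels.grid.spacing
    indicator = labels.solvent_mask.astype(float)
    return naive_gaussian_blur(indicator, params.dog_sigma_small / s) - naive_gaussian_blur(
        indicator, params.dog_sigma_large / s
    )


def naive_psp(labels: LabelField) -> np.ndarray:
    """Per-voxel protein-solvent-protein counts by walking every scan line."""
    mac = labels.macromolecule_mask
    shape = mac.shape
    out = np.zeros(shape, dtype=np.int8)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if mac[i, j, k]:
                    continue
                count = 0
                for d in SCAN_DIRECTIONS:
                    flanked_both = True
                    for sign in (1, -1):
                        hit = False
                        x, y, z = i + sign * d[0], j + sign * d[1], k + sign * d[2]
                        while 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
                            if mac[x, y, z]:
                                hit = True
                                break
                            x, y, z = x + sign * d[0], y + sign * d[1], z + sign * d[2]
                        if not hit:
                            flanked_both = False
                            break
                    if flanked_both:
                        count += 1
                out[i, j, k] = count
    return out


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(seeds: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a boolean mask by breadth-first flood fill."""
    offs = _neighbor_offsets(connectivity)
    shape = seeds.shape
    visited = np.zeros(shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(seeds)):
        if visited[start]:
            continue
        comp = set()
        queue = deque([start])
        visited[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offs:
                u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= u[a] < shape[a] for a in range(3)) and seeds[u] and not visited[u]:
                    visited[u] = True
                    queue.append(u)
        components.append(comp)
    return components


def _percolating_voxels_at_level(passable: np.ndarray) -> np.ndarray:
    """Voxels belonging to a periodic component that touches its own lattice
    translate, found by BFS with per-voxel lattice-offset bookkeeping."""
    shape = passable.shape
    result = np.zeros(shape, dtype=bool)
    seen = np.zeros(shape, dtype=bool)
    for start in map(tuple, np.argwhere(passable)):
        if seen[start]:
            continue
        offsets = {start: (0, 0, 0)}
        seen[start] = True
        queue = deque([start])
        members = [start]
        percolates = False
        while queue:
            v = queue.popleft()
            ov = offsets[v]
            for axis in range(3):
                for step in (1, -1):
                    u = list(v)
                    raw = v[axis] + step
                    wrap = raw // shape[axis]
                    u[axis] = raw % shape[axis]
                    u = tuple(u)
                    if not passable[u]:
                        continue
                    ou = list(ov)
                    ou[axis] += wrap
                    ou = tuple(ou)
                    if u in offsets:
                        if offsets[u] != ou:
                            percolates = True
                    else:
                        offsets[u] = ou
                        seen[u] = True
                        members.append(u)
                        queue.append(u)
        if percolates:
            for v in members:
                result[v] = True
    return result


def naive_local_bottleneck(clearance: np.ndarray) -> np.ndarray:
    """Local bottleneck radii by explicit search over threshold levels.

    For each distinct positive clearance level r (descending): threshold the
    field at r, find the percolating periodic components, and record r for
    every still-unassigned voxel inside one.
    """
    out = np.zeros_like(clearance, dtype=float)
    levels = np.unique(clearance[clearance > 0])[::-1]
    for r in levels:
        perc = _percolating_voxels_at_level(clearance >= r)
        newly = perc & (out == 0)
        out[newly] = r
    return out
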