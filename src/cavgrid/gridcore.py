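"""Voxel grids: construction, orientation standardization, annotation, CCP4 I/O.

A :class:`VoxelGrid` is an axis-aligned isotropic lattice; the world position of
voxel (i, j, k) is ``origin + spacing * (i, j, k)``. Structures are rotated into
a principal-axes frame before gridding so that the grid is as small as possible
and pocket prediction does not depend on the input orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import gemmi

from .structure_io import Atom, Structure, StructureError, UnitCell

__all__ = [
    "MACROMOLECULE",
    "SOLVENT",
    "VoxelGrid",
    "LabelField",
    "ScalarField",
    "CountField",
    "OrientationTransform",
    "DegenerateGeometryError",
    "standardize_orientation",
    "build_grid",
    "annotate_occupancy",
    "write_ccp4",
    "read_ccp4",
]

SOLVENT = 0
MACROMOLECULE = 1


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate for PCA (coincident/collinear)."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned isotropic voxel lattice."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape components must be >= 1")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (Å) of voxel index triples, shape (..., 3)."""
        return np.asarray(self.origin) + self.spacing * np.asarray(indices, dtype=float)

    def index_of(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points (not clipped to the grid)."""
        rel = (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.spacing
        return np.rint(rel).astype(int)

    def all_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel, shape grid.shape + (3,)."""
        axes = [np.asarray(self.origin)[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        out = np.empty(self.shape + (3,))
        out[..., 0] = axes[0][:, None, None]
        out[..., 1] = axes[1][None, :, None]
        out[..., 2] = axes[2][None, None, :]
        return out


def _check_same_grid(grid: VoxelGrid, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"field shape {values.shape} != grid shape {grid.shape}")
    return values


@dataclass
class LabelField:
    """Per-voxel MACROMOLECULE/SOLVENT annotation."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = _check_same_grid(self.grid, self.labels).astype(np.uint8)

    @property
    def solvent_mask(self) -> np.ndarray:
        return self.labels == SOLVENT

    @property
    def macromolecule_mask(self) -> np.ndarray:
        return self.labels == MACROMOLECULE


@dataclass
class ScalarField:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_same_grid(self.grid, self.values).astype(float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar field contains non-finite values")


@dataclass
class CountField:
    """Per-voxel protein-solvent-protein event counts (0..7)."""

    grid: VoxelGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = _check_same_grid(self.grid, self.counts).astype(np.int8)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > 7:
            raise ValueError("PSP counts must lie in [0, 7]")


@dataclass(frozen=True)
class OrientationTransform:
    """Rigid map ``x' = R x + t`` from original to standardized coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def apply_inverse(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.translation) @ self.rotation


_SIGN_TOL = 1e-9


def standardize_orientation(structure: Structure) -> tuple[Structure, OrientationTransform]:
    """Rotate a structure into its principal-axes frame.

    The centroid moves to the origin and the covariance eigenvectors align with
    the lattice axes, largest variance first, so the bounding box (and hence
    the grid) is minimal and downstream results are orientation-invariant.
    Axis signs are fixed by the sign of the third central moment along each
    axis (falling back to the dominant eigenvector component on ties), and the
    rotation determinant is forced to +1.
    """
    heavy = structure.heavy_atoms()
    if len(heavy) < 3:
        raise DegenerateGeometryError("need at least 3 heavy atoms for orientation standardization")
    X = np.array([a.coords for a in heavy], dtype=float)
    centroid = X.mean(axis=0)
    Xc = X - centroid
    cov = Xc.T @ Xc / len(Xc)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-10 * max(evals[0], 1.0):
        raise DegenerateGeometryError("point set is collinear or coincident; cannot orient")
    axes = evecs.T.copy()  # rows are principal axes
    proj = Xc @ axes.T
    m3 = (proj**3).mean(axis=0)
    signs = np.ones(3)
    for k in range(3):
        if m3[k] > _SIGN_TOL:
            signs[k] = 1.0
        elif m3[k] < -_SIGN_TOL:
            signs[k] = -1.0
        else:
            # tie-break: make the largest-magnitude eigenvector component positive
            v = axes[k]
            signs[k] = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
    R = signs[:, None] * axes
    if np.linalg.det(R) < 0:
        k = int(np.argmin(np.abs(m3)))  # flip the least-committed axis
        R[k] = -R[k]
    t = -R @ centroid
    transform = OrientationTransform(rotation=R, translation=t)
    new_struct = structure.with_coords(transform.apply(structure.coords()))
    return new_struct, transform


def build_grid(structure: Structure, spacing: float = 0.5, padding: float = 3.0) -> VoxelGrid:
    """Grid covering the heavy-atom bounding box extended by ``padding`` per side."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding < 0:
        raise ValueError("padding must be non-negative")
    heavy = structure.heavy_atoms()
    if not heavy:
        raise StructureError("cannot build a grid for an empty structure")
    X = np.array([a.coords for a in heavy], dtype=float)
    lo = X.min(axis=0) - padding
    hi = X.max(axis=0) + padding
    extent = hi - lo
    shape = tuple(int(np.ceil(e / spacing)) + 1 for e in extent)
    return VoxelGrid(origin=tuple(lo), spacing=spacing, shape=shape)


def annotate_occupancy(
    grid: VoxelGrid,
    structure: Structure,
    solvent_margin: float = 0.0,
) -> LabelField:
    """Label voxels by occupancy: MACROMOLECULE where the distance to the
    nearest heavy-atom center is <= that atom's van der Waals radius plus
    ``solvent_margin``, SOLVENT otherwise."""
    mac = np.zeros(grid.shape, dtype=bool)
    origin = np.asarray(grid.origin)
    inv = 1.0 / grid.spacing
    shape = np.asarray(grid.shape)
    for atom in structure.heavy_atoms():
        r = atom.vdw_radius + solvent_margin
        if r <= 0:
            continue
        c = (atom.xyz - origin) * inv
        rv = r * inv
        lo = np.maximum(np.ceil(c - rv), 0).astype(int)
        hi = np.minimum(np.floor(c + rv), shape - 1).astype(int)
        if np.any(lo > hi):
            continue
        ii = np.arange(lo[0], hi[0] + 1)
        jj = np.arange(lo[1], hi[1] + 1)
        kk = np.arange(lo[2], hi[2] + 1)
        d2 = (
            (ii - c[0])[:, None, None] ** 2
            + (jj - c[1])[None, :, None] ** 2
            + (kk - c[2])[None, None, :] ** 2
        )
        sub = mac[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        sub |= d2 <= rv * rv + 1e-12
        mac[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = sub
    return LabelField(grid=grid, labels=mac.astype(np.uint8))


# ---------------------------------------------------------------------------
# CCP4 maps (via gemmi; MRC2014-compatible, mode 2 float, axis order X,Y,Z)


def write_ccp4(field: ScalarField, path: str | Path, unit_cell: UnitCell | None = None) -> None:
    """Write a scalar field as a CCP4/MRC map (mode 2, 32-bit float).

    Without an explicit ``unit_cell`` the map cell is the orthogonal box
    ``spacing * shape`` (one grid step per map division); the grid origin is
    stored in the MRC origin header words so a round trip restores it.
    """
    values = np.ascontiguousarray(field.values, dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(values)
    if unit_cell is not None:
        m.grid.unit_cell = gemmi.UnitCell(
            unit_cell.a, unit_cell.b, unit_cell.c,
            unit_cell.alpha, unit_cell.beta, unit_cell.gamma,
        )
    else:
        nx, ny, nz = field.grid.shape
        s = field.grid.spacing
        m.grid.unit_cell = gemmi.UnitCell(nx * s, ny * s, nz * s, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P 1")
    m.update_ccp4_header()
    ox, oy, oz = field.grid.origin
    m.set_header_float(50, float(ox))
    m.set_header_float(51, float(oy))
    m.set_header_float(52, float(oz))
    m.write_ccp4_map(str(path))


def read_ccp4(path: str | Path) -> ScalarField:
    """Read a CCP4/MRC map written by :func:`write_ccp4` back into a ScalarField."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such map file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to read CCP4 map {path}: {exc}") from exc
    values = np.array(m.grid, copy=True)
    shape = values.shape
    cell = m.grid.unit_cell
    spacing = cell.a / shape[0]
    origin = (m.header_float(50), m.header_float(51), m.header_float(52))
    grid = VoxelGrid(origin=origin, spacing=spacing, shape=tuple(shape))
    return ScalarField(grid=grid, values=values.astype(float))
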