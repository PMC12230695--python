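"""Solvent-channel analysis of crystal structures.

The crystal's unit cell is filled by symmetry expansion of the asymmetric
unit, a periodic clearance field is computed (largest probe fitting at each
grid point without touching a van der Waals sphere), and a widest-path
percolation sweep converts clearance into the *local bottleneck radius*: the
largest spherical probe that can reach each grid point from infinity along a
periodic path through the crystal, accounting for constrictions anywhere along
the way. The maximum of that field is the overall bottleneck radius — the
largest probe that can diffuse through the crystal at all — the quantity that
decides whether a soaking compound can reach a binding site.

Percolation is detected with an offset-tracking union-find (Kruskal-style
sweep over voxels in order of decreasing clearance): a component percolates as
soon as a union closes a cycle whose net lattice offset is non-zero, i.e. the
component touches one of its own lattice translates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    LigandSelection,
    SelectionError,
    Structure,
    StructureError,
    UnitCell,
    extract_ligand,
    parse_symmetry,
)
from .gridcore import ScalarField, write_ccp4
from .pockets import PocketParams, PocketSet, detect_pockets
from .descriptors import coverage, mouth_voxels

__all__ = [
    "PeriodicGrid",
    "ChannelField",
    "ChannelResult",
    "make_periodic_grid",
    "expand_unit_cell",
    "periodic_clearance",
    "local_bottleneck_field",
    "site_radii",
    "run_channels",
]

#: symmetry images closer than this (Å) are treated as the same special-position atom
SPECIAL_POSITION_TOL = 0.3


@dataclass(frozen=True)
class PeriodicGrid:
    """Fractional-coordinate voxel lattice covering one unit cell.

    Voxel (i, j, k) sits at fractional coordinates (i/nx, j/ny, k/nz); index
    arithmetic wraps modulo the shape. The actual step per axis is the cell
    edge divided by an integer subdivision near the requested target spacing.
    """

    unit_cell: UnitCell
    shape: tuple[int, int, int]
    target_spacing: float
    periodic: bool = True

    @property
    def origin(self) -> tuple[float, float, float]:
        return (0.0, 0.0, 0.0)

    @property
    def axis_spacings(self) -> tuple[float, float, float]:
        L = self.unit_cell.lengths
        return tuple(L[d] / self.shape[d] for d in range(3))

    @property
    def spacing(self) -> float:
        """Representative (mean) step in Å, used for ± one-voxel tolerances."""
        return float(np.mean(self.axis_spacings))

    def fractional_coords(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return idx / np.asarray(self.shape, dtype=float)

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        return self.unit_cell.orthogonalize(self.fractional_coords(indices))

    def all_world_coords(self) -> np.ndarray:
        nx, ny, nz = self.shape
        I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([I, J, K], axis=-1).reshape(-1, 3)
        return self.world_coords(idx).reshape(nx, ny, nz, 3)

    def index_of_world(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest periodic voxel index of world points (wrapped into the cell)."""
        frac = self.unit_cell.fractionalize(xyz) % 1.0
        idx = np.rint(frac * np.asarray(self.shape)).astype(int)
        return idx % np.asarray(self.shape)


@dataclass
class ChannelField:
    """Per-voxel local bottleneck radii on a periodic grid."""

    grid: PeriodicGrid
    local_bottleneck: np.ndarray

    def __post_init__(self) -> None:
        self.local_bottleneck = np.asarray(self.local_bottleneck, dtype=float)
        if self.local_bottleneck.shape != self.grid.shape:
            raise ValueError("field shape does not match grid shape")


@dataclass
class ChannelResult:
    field: ChannelField
    overall_bottleneck: float
    inner_site_radius: float | None = None
    outer_site_radius: float | None = None

    def to_summary(self) -> dict:
        return {
            "overall_bottleneck_A": round(self.overall_bottleneck, 4),
            "inner_site_radius_A": None
            if self.inner_site_radius is None
            else round(self.inner_site_radius, 4),
            "outer_site_radius_A": None
            if self.outer_site_radius is None
            else round(self.outer_site_radius, 4),
            "grid_shape": list(self.field.grid.shape),
            "grid_spacing_A": round(self.field.grid.spacing, 4),
        }


def make_periodic_grid(
    unit_cell: UnitCell, spacing: float = 0.8, min_dim: int = 16
) -> PeriodicGrid:
    """Periodic grid with integer subdivisions closest to the target spacing
    (at least ``min_dim`` per axis)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    shape = tuple(
        max(min_dim, int(round(L / spacing))) for L in unit_cell.lengths
    )
    return PeriodicGrid(unit_cell=unit_cell, shape=shape, target_spacing=spacing)


# ---------------------------------------------------------------------------
# symmetry expansion


def expand_unit_cell(structure: Structure) -> Structure:
    """All symmetry images of the asymmetric unit wrapped into [0,1)³.

    Images of the same source atom closer than ``SPECIAL_POSITION_TOL`` (Å,
    minimum-image) collapse to one copy (special positions).
    """
    cell = parse_symmetry(structure)
    ops = cell.operator_arrays()
    if not ops:
        raise StructureError("unit cell has no symmetry operators")
    M = cell.orthogonalization_matrix
    atoms_out: list[Atom] = []
    serial = 0
    for atom in structure.atoms:
        frac = cell.fractionalize(atom.xyz)
        kept_fracs: list[np.ndarray] = []
        for R, t in ops:
            f = (R @ frac + t) % 1.0
            dup = False
            for g in kept_fracs:
                delta = f - g
                delta -= np.rint(delta)
                if np.linalg.norm(M @ delta) < SPECIAL_POSITION_TOL:
                    dup = True
                    break
            if dup:
                continue
            kept_fracs.append(f)
            serial += 1
            atoms_out.append(replace(atom, serial=serial, coords=tuple(M @ f)))
    if not atoms_out:
        raise StructureError("symmetry expansion produced no atoms")
    return Structure(atoms_out, unit_cell=cell, source_id=structure.source_id + ":cell")


# ---------------------------------------------------------------------------
# clearance


_NEIGHBOR_CELLS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], dtype=float
)


def periodic_clearance(
    grid: PeriodicGrid, cell_atoms: Structure, cap: float | None = None
) -> ScalarField:
    """Clearance field: for each voxel, ``min over atoms (dist - vdW radius)``
    with atoms replicated in the 26 neighboring cells, clamped to [0, cap].

    The cap defaults to half the shortest cell edge — a probe larger than that
    cannot be meaningfully periodic at this resolution. An empty cell yields
    the cap everywhere.
    """
    if cap is None:
        cap = min(grid.unit_cell.lengths) / 2.0
    voxels = grid.all_world_coords().reshape(-1, 3)
    heavy = cell_atoms.heavy_atoms()
    clearance = np.full(len(voxels), cap, dtype=float)
    if heavy:
        cell = grid.unit_cell
        M = cell.orthogonalization_matrix
        shifts = (_NEIGHBOR_CELLS @ M.T)
        by_radius: dict[float, list[np.ndarray]] = {}
        for a in heavy:
            # wrap into the cell so lattice translations of the input are no-ops
            wrapped = cell.orthogonalize(cell.fractionalize(a.xyz) % 1.0)
            by_radius.setdefault(round(a.vdw_radius, 6), []).append(wrapped)
        for r, pts in by_radius.items():
            pts = np.asarray(pts)
            images = (pts[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
            tree = cKDTree(images)
            d, _ = tree.query(voxels, k=1)
            clearance = np.minimum(clearance, d - r)
    clearance = np.clip(clearance, 0.0, cap)
    return ScalarField(grid=grid, values=clearance.reshape(grid.shape))


# ---------------------------------------------------------------------------
# widest-path percolation sweep


def _periodic_neighbor_tables(shape: tuple[int, int, int]):
    """Flat neighbor indices and lattice-wrap offsets for the 6 face directions."""
    nx, ny, nz = shape
    N = nx * ny * nz
    I, J, K = np.unravel_index(np.arange(N), shape)
    coords = (I, J, K)
    dims = (nx, ny, nz)
    tables = []
    for axis in range(3):
        for step in (1, -1):
            moved = [coords[0].copy(), coords[1].copy(), coords[2].copy()]
            raw = coords[axis] + step
            wrap = raw // dims[axis]  # -1, 0, or +1
            moved[axis] = raw % dims[axis]
            flat = np.ravel_multi_index(moved, shape)
            offset = np.zeros((N, 3), dtype=np.int8)
            offset[:, axis] = wrap
            tables.append((flat.astype(np.int64), offset))
    return tables


def local_bottleneck_field(clearance: ScalarField) -> ChannelField:
    """Exact local-bottleneck radii by a decreasing-clearance union-find sweep.

    Voxels are activated in order of decreasing clearance and joined to active
    6-connected periodic neighbors. Each node carries its integer lattice
    offset relative to its component root; a union closing a cycle with a
    non-zero net offset proves the component connects to its own translate,
    i.e. percolates. A voxel's local bottleneck radius is the sweep level at
    which it first belongs to a percolating component (0 if never).
    """
    grid = clearance.grid
    shape = grid.shape
    c = clearance.values.ravel()
    N = c.size
    nbr_tables = _periodic_neighbor_tables(shape)
    order = np.argsort(-c, kind="stable")
    parent = np.arange(N, dtype=np.int64)
    off = np.zeros((N, 3), dtype=np.int64)
    comp_size = np.ones(N, dtype=np.int64)
    percolating = np.zeros(N, dtype=bool)
    active = np.zeros(N, dtype=bool)
    pending: dict[int, list[int]] = {}
    out = np.zeros(N, dtype=float)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        node = x
        path = []
        while parent[node] != node:
            path.append(node)
            node = parent[node]
        for y in reversed(path):
            p = parent[y]
            if p != root:
                off[y] += off[p]
                parent[y] = root
        return root

    def flush(root: int, level: float) -> None:
        for v in pending.pop(root, ()):  # assign first-percolation level
            out[v] = level

    for v in order:
        level = c[v]
        if level <= 0.0:
            break
        active[v] = True
        pending[v] = [v]
        for flat, offsets in nbr_tables:
            u = int(flat[v])
            if not active[u]:
                continue
            w = offsets[v].astype(np.int64)
            rv = find(v)
            ru = find(u)
            if rv == ru:
                if not np.array_equal(off[u], off[v] + w):
                    if not percolating[rv]:
                        percolating[rv] = True
                        flush(rv, level)
                continue
            # attach the smaller component under the larger
            if comp_size[rv] >= comp_size[ru]:
                big, small = rv, ru
                off[small] = off[v] + w - off[u]
            else:
                big, small = ru, rv
                off[small] = off[u] - w - off[v]
            parent[small] = big
            comp_size[big] += comp_size[small]
            was_perc = percolating[big] or percolating[small]
            percolating[big] = was_perc
            pend_small = pending.pop(small, [])
            if was_perc:
                flush(big, level)
                for x in pend_small:
                    out[x] = level
            else:
                pending.setdefault(big, []).extend(pend_small)
        r = find(v)
        if percolating[r]:
            flush(r, level)
    return ChannelField(grid=grid, local_bottleneck=out.reshape(shape))


# ---------------------------------------------------------------------------
# active-site radii


def _min_image_distance_to_points(grid: PeriodicGrid, points: np.ndarray) -> np.ndarray:
    """Minimum-image distance from every voxel to the nearest of ``points``."""
    M = grid.unit_cell.orthogonalization_matrix
    shifts = _NEIGHBOR_CELLS @ M.T
    frac = grid.unit_cell.fractionalize(np.atleast_2d(points)) % 1.0
    wrapped = grid.unit_cell.orthogonalize(frac)
    images = (wrapped[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree = cKDTree(images)
    voxels = grid.all_world_coords().reshape(-1, 3)
    d, _ = tree.query(voxels, k=1)
    return d.reshape(grid.shape)


def site_radii(
    field: ChannelField,
    ligand: LigandSelection,
    pockets: PocketSet,
    mouth_shell: float = 5.0,
    ligand_region_radius: float = 3.0,
) -> tuple[float, float]:
    """Inner and outer active-site bottleneck radii for a chosen ligand.

    inner: largest probe that can reach the ligand site — the max local
    bottleneck radius over periodic voxels within ``ligand_region_radius`` of
    a ligand heavy atom. outer: the bottleneck radius in front of the pocket —
    the max over voxels within ``mouth_shell`` Å outside the mouth of the
    ligand's pocket (the pocket with the highest ligand coverage). Either is 0
    when no percolating path reaches the region.
    """
    lb = field.local_bottleneck
    grid = field.grid
    d_lig = _min_image_distance_to_points(grid, ligand.coords())
    region = d_lig <= ligand_region_radius
    inner = float(lb[region].max()) if region.any() else 0.0

    if pockets.labels is None or not pockets.pockets:
        raise SelectionError("no pockets available to define the site mouth")
    std_ligand = ligand
    if pockets.transform is not None:
        std_ligand = LigandSelection(
            atoms=tuple(
                replace(a, coords=tuple(pockets.transform.apply(a.xyz)))
                for a in ligand.atoms
            ),
            selector=ligand.selector,
        )
    best = None
    best_cov = -1.0
    for p in pockets.pockets:
        try:
            lc, _ = coverage(p, std_ligand, pockets.grid, pockets.labels)
        except SelectionError:
            lc = 0.0
        if lc > best_cov:
            best_cov = lc
            best = p
    if best is None or best_cov <= 0.0:
        raise SelectionError("ligand is not covered by any detected pocket")
    mouths = mouth_voxels(best, pockets.labels)
    if len(mouths) == 0:
        return inner, 0.0
    mouth_world = pockets.grid.world_coords(mouths)
    if pockets.transform is not None:
        mouth_world = pockets.transform.apply_inverse(mouth_world)
    d_mouth = _min_image_distance_to_points(grid, mouth_world)
    pocket_world = pockets.voxel_world_coords(best, original_frame=True)
    pocket_idx = grid.index_of_world(pocket_world)
    in_pocket = np.zeros(grid.shape, dtype=bool)
    in_pocket[pocket_idx[:, 0], pocket_idx[:, 1], pocket_idx[:, 2]] = True
    shell = (d_mouth <= mouth_shell) & ~in_pocket
    outer = float(lb[shell].max()) if shell.any() else 0.0
    return inner, outer


# ---------------------------------------------------------------------------
# orchestration


def run_channels(
    structure: Structure,
    ligand: str | LigandSelection | None = None,
    spacing: float = 0.8,
    include_hetero: bool = True,
    include_waters: bool = False,
    pocket_params: PocketParams | None = None,
    map_path: str | Path | None = None,
) -> ChannelResult:
    """Full channel analysis of one crystallographic unit cell.

    Requires CRYST1 and symmetry. Waters are excluded from the blocking atoms
    by default (other HETATM are included); a selected reference ligand is
    always excluded so the probe can reach its site. The optional CCP4 map
    stores the local bottleneck radius so that thresholding the map at a
    cut-off shows every point reachable by a probe of that radius.
    """
    cell = parse_symmetry(structure)
    lig: LigandSelection | None
    lig = extract_ligand(structure, ligand) if isinstance(ligand, str) else ligand
    exclude = [lig.residue_key] if lig is not None else []
    blockers = structure.receptor_atoms(
        include_hetero=include_hetero,
        include_waters=include_waters,
        exclude_residues=exclude,
    )
    if not blockers:
        raise StructureError("no blocking atoms for channel analysis")
    expanded = expand_unit_cell(structure.subset(blockers))
    grid = make_periodic_grid(cell, spacing=spacing)
    clearance = periodic_clearance(grid, expanded)
    field = local_bottleneck_field(clearance)
    overall = float(field.local_bottleneck.max())
    inner = outer = None
    if lig is not None:
        pocket_set = detect_pockets(structure, params=pocket_params, ligand=lig)
        inner, outer = site_radii(field, lig, pocket_set)
    result = ChannelResult(
        field=field, overall_bottleneck=overall,
        inner_site_radius=inner, outer_site_radius=outer,
    )
    if map_path is not None:
        sf = ScalarField(grid=grid, values=field.local_bottleneck)
        write_ccp4(sf, map_path, unit_cell=cell)
    return result


def write_summary(result: ChannelResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_summary(), indent=2, sort_keys=True) + "\n")
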