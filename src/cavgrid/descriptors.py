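"""Per-pocket properties: volume, surface, depth, lining residues, coverage.

All quantities are voxel-based. Volume is voxel count times spacing³; surface
counts exposed voxel faces; depth is the largest distance from a pocket voxel
to the pocket mouth (the voxels bordering outside solvent). Ligand and pocket
coverage are volumetric overlap fractions between the pocket voxel set and the
solvent voxels occupied by the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import LigandSelection, SelectionError, Structure
from .gridcore import LabelField, VoxelGrid
from .pockets import Pocket, PocketSet, ligand_voxel_mask

__all__ = [
    "PocketDescriptors",
    "pocket_volume",
    "pocket_surface",
    "pocket_depth",
    "mouth_voxels",
    "coverage",
    "lining_residues",
    "compute_descriptors",
    "descriptor_table",
]

_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class PocketDescriptors:
    pocket_id: int
    volume: float  # Å³
    surface: float  # Å²
    depth: float  # Å
    voxel_count: int
    centroid: tuple[float, float, float]  # Å, original structure frame
    lining_residues: list[tuple[str, str, int]]
    ligand_coverage: float | None = None
    pocket_coverage: float | None = None


def pocket_volume(pocket: Pocket, spacing: float) -> float:
    """V = voxel count · spacing³ (Å³)."""
    return pocket.volume(spacing)


def pocket_surface(pocket: Pocket, labels: LabelField) -> float:
    """Exposed-face area: faces between a pocket voxel and any non-pocket voxel
    (the grid boundary counts as non-pocket) times spacing²."""
    shape = labels.grid.shape
    mask = pocket.mask(shape)
    faces = 0
    for d in _FACE_NEIGHBORS:
        shifted = _shift_bool(mask, tuple(d))
        faces += int(np.count_nonzero(mask & ~shifted))
    return faces * labels.grid.spacing**2


def _shift_bool(arr: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step == 1:
            src[ax] = slice(0, -1)
            dst[ax] = slice(1, None)
        elif step == -1:
            src[ax] = slice(1, None)
            dst[ax] = slice(0, -1)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def mouth_voxels(pocket: Pocket, labels: LabelField) -> np.ndarray:
    """Pocket voxels with at least one 6-connected solvent neighbor outside the
    pocket — the opening toward bulk solvent. Shape (m, 3); may be empty."""
    shape = labels.grid.shape
    mask = pocket.mask(shape)
    outside_solvent = labels.solvent_mask & ~mask
    mouth = np.zeros(shape, dtype=bool)
    for d in _FACE_NEIGHBORS:
        # neighbor in direction d is outside solvent -> this voxel is a mouth voxel
        mouth |= mask & _shift_bool(outside_solvent, tuple(-d))
    return np.argwhere(mouth)


def pocket_depth(pocket: Pocket, labels: LabelField) -> float:
    """Max distance (Å) from any pocket voxel to the nearest mouth voxel.

    A fully enclosed pocket (no mouth) falls back to half its maximum pairwise
    extent.
    """
    spacing = labels.grid.spacing
    pts = pocket.voxel_indices * spacing
    mouths = mouth_voxels(pocket, labels)
    if len(mouths) == 0:
        return _max_pairwise_distance(pts) / 2.0
    tree = cKDTree(mouths * spacing)
    dists, _ = tree.query(pts, k=1)
    return float(np.max(dists))


def _max_pairwise_distance(pts: np.ndarray) -> float:
    if len(pts) == 1:
        return 0.0
    if len(pts) > 400:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (flat) sets: fall through to brute force
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def coverage(
    pocket: Pocket,
    ligand: LigandSelection,
    grid: VoxelGrid,
    labels: LabelField,
) -> tuple[float, float]:
    """Volumetric (ligand_coverage, pocket_coverage).

    The ligand voxel set is the solvent voxels within the vdW radius of any
    ligand heavy atom (ligand coordinates must be in the grid frame).
    ligand_coverage = |ligand ∩ pocket| / |ligand|;
    pocket_coverage = |ligand ∩ pocket| / |pocket|.
    """
    lig_mask = ligand_voxel_mask(grid, ligand) & labels.solvent_mask
    n_lig = int(np.count_nonzero(lig_mask))
    if n_lig == 0:
        raise SelectionError(
            "ligand occupies no solvent voxels on this grid (outside the grid or buried)"
        )
    pmask = pocket.mask(grid.shape)
    inter = int(np.count_nonzero(lig_mask & pmask))
    return inter / n_lig, inter / pocket.n_voxels


def lining_residues(
    pocket: Pocket,
    structure: Structure,
    grid: VoxelGrid,
    cutoff: float = 4.0,
    transform=None,
) -> list[tuple[str, str, int]]:
    """Residues with at least one heavy atom within ``cutoff`` Å of a pocket
    voxel center, unique, ordered by chain then residue number.

    ``transform`` (an OrientationTransform) maps voxel centers back into the
    structure's frame when the grid was built in a standardized orientation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    centers = grid.world_coords(pocket.voxel_indices)
    if transform is not None:
        centers = transform.apply_inverse(centers)
    tree = cKDTree(centers)
    found: set[tuple[str, int, str, str]] = set()
    for atom in structure.heavy_atoms():
        if tree.query_ball_point(atom.xyz, cutoff, return_length=True) > 0:
            found.add((atom.chain_id, atom.residue_number, atom.insertion_code, atom.residue_name))
    ordered = sorted(found)
    return [(c, rn, num) for (c, num, _icode, rn) in ordered]


def compute_descriptors(pocket_set: PocketSet, lining_cutoff: float = 4.0) -> list[PocketDescriptors]:
    """Descriptors for every pocket of a detection result (original frame)."""
    out = []
    labels = pocket_set.labels
    if labels is None:
        raise ValueError("pocket set carries no label field")
    spacing = pocket_set.grid.spacing
    std_ligand = None
    if pocket_set.ligand is not None and pocket_set.transform is not None:
        from dataclasses import replace as _replace

        std_ligand = LigandSelection(
            atoms=tuple(
                _replace(a, coords=tuple(pocket_set.transform.apply(a.xyz)))
                for a in pocket_set.ligand.atoms
            ),
            selector=pocket_set.ligand.selector,
        )
    elif pocket_set.ligand is not None:
        std_ligand = pocket_set.ligand
    for p in pocket_set.pockets:
        centers = pocket_set.voxel_world_coords(p, original_frame=True)
        lc = pc = None
        if std_ligand is not None:
            try:
                lc, pc = coverage(p, std_ligand, pocket_set.grid, labels)
            except SelectionError:
                lc = pc = 0.0
        lining = []
        if pocket_set.structure is not None:
            lining = lining_residues(
                p, pocket_set.structure, pocket_set.grid, cutoff=lining_cutoff,
                transform=pocket_set.transform,
            )
        out.append(
            PocketDescriptors(
                pocket_id=p.rank,
                volume=pocket_volume(p, spacing),
                surface=pocket_surface(p, labels),
                depth=pocket_depth(p, labels),
                voxel_count=p.n_voxels,
                centroid=tuple(np.round(centers.mean(axis=0), 6)),
                lining_residues=lining,
                ligand_coverage=lc,
                pocket_coverage=pc,
            )
        )
    return out


def descriptor_table(descriptors: list[PocketDescriptors]) -> pd.DataFrame:
    """Tabular (TSV-ready) form of pocket descriptors."""
    rows = []
    for d in descriptors:
        rows.append(
            {
                "pocket_id": d.pocket_id,
                "volume_A3": round(d.volume, 3),
                "surface_A2": round(d.surface, 3),
                "depth_A": round(d.depth, 3),
                "n_voxels": d.voxel_count,
                "centroid_x": round(d.centroid[0], 3),
                "centroid_y": round(d.centroid[1], 3),
                "centroid_z": round(d.centroid[2], 3),
                "n_lining_residues": len(d.lining_residues),
                "ligand_coverage": "" if d.ligand_coverage is None else round(d.ligand_coverage, 4),
                "pocket_coverage": "" if d.pocket_coverage is None else round(d.pocket_coverage, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pocket_id", "volume_A3", "surface_A2", "depth_A", "n_voxels",
            "centroid_x", "centroid_y", "centroid_z", "n_lining_residues",
            "ligand_coverage", "pocket_coverage",
        ],
    )
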