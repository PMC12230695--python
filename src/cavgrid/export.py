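"""File export of detection results: per-pocket PDB and CCP4 mask, TSV table."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .structure_io import Atom, Structure
from .gridcore import ScalarField, write_ccp4
from .pockets import Pocket, PocketSet
from .descriptors import compute_descriptors, descriptor_table

__all__ = ["write_pocket_pdb", "write_pocket_mask", "write_pocket_outputs"]


def write_pocket_pdb(pocket_set: PocketSet, pocket: Pocket, path: str | Path) -> None:
    """Pocket as pseudo-atoms at voxel centers (element H, residue POK),
    in the original structure frame so it overlays the input."""
    centers = pocket_set.voxel_world_coords(pocket, original_frame=True)
    atoms = [
        Atom(
            serial=i + 1,
            name="H",
            element="H",
            coords=tuple(np.round(c, 3)),
            chain_id="P",
            residue_name="POK",
            residue_number=pocket.rank if pocket.rank else 1,
            is_hetero=True,
        )
        for i, c in enumerate(centers)
    ]
    from .structure_io import write_structure

    write_structure(Structure(atoms, source_id=f"pocket_{pocket.rank}"), path)


def write_pocket_mask(pocket_set: PocketSet, pocket: Pocket, path: str | Path) -> None:
    """Binary CCP4 mask (1 inside the pocket, 0 outside) on the detection grid.

    The grid lives in the standardized (principal-axes) frame; the run manifest
    records the transform back to the input frame.
    """
    mask = pocket.mask(pocket_set.grid.shape).astype(float)
    write_ccp4(ScalarField(grid=pocket_set.grid, values=mask), path)


def write_pocket_outputs(pocket_set: PocketSet, out_dir: str | Path) -> dict:
    """Write descriptor TSV plus one PDB and one CCP4 mask per pocket.

    Returns a manifest fragment listing the files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    descriptors = compute_descriptors(pocket_set)
    table = descriptor_table(descriptors)
    tsv_path = out_dir / "pockets.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)
    files = {"descriptor_table": tsv_path.name, "pockets": []}
    for pocket in pocket_set.pockets:
        pdb_path = out_dir / f"pocket_{pocket.rank:02d}.pdb"
        map_path = out_dir / f"pocket_{pocket.rank:02d}.ccp4"
        write_pocket_pdb(pocket_set, pocket, pdb_path)
        write_pocket_mask(pocket_set, pocket, map_path)
        files["pockets"].append({"rank": pocket.rank, "pdb": pdb_path.name, "ccp4": map_path.name})
    return files
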