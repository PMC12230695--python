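"""Reading, writing and selecting macromolecular structures.

The in-memory model is deliberately flat: a :class:`Structure` is a list of
:class:`Atom` records plus an optional crystallographic :class:`UnitCell`.
Parsing of PDB/mmCIF files and space-group operator lookup is delegated to
gemmi; everything downstream (grids, pockets, channels) only sees these types.

Conventions
-----------
* Coordinates are orthogonal Ångström, right-handed.
* Alternate locations: only blank or 'A' conformers are kept, so the grid is
  built from a single deterministic conformer.
* Hydrogens are carried through parsing but ignored by every geometric
  computation (the methods are heavy-atom based); :meth:`Structure.heavy_atoms`
  and :func:`extract_ligand` drop them.
* Waters are retained but flagged by residue name and excluded from the
  receptor by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:
    import gemmi
except ImportError as exc:  # pragma: no cover
    raise ImportError("cavgrid requires gemmi for structure and map I/O") from exc

__all__ = [
    "Atom",
    "UnitCell",
    "Structure",
    "LigandSelection",
    "StructureError",
    "SelectionError",
    "MissingSymmetryError",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "WATER_RESIDUES",
    "vdw_radius",
    "read_structure",
    "write_structure",
    "select_chains",
    "extract_ligand",
    "parse_symmetry",
]

#: Van der Waals radii (Å) used for occupancy annotation and clearance fields.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})


class StructureError(ValueError):
    """Raised for unreadable, empty, or malformed structures."""


class SelectionError(ValueError):
    """Raised when a chain or ligand selection matches nothing (or too much)."""


class MissingSymmetryError(StructureError):
    """Raised when crystallographic analysis is requested without CRYST1/symmetry."""


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass(frozen=True)
class Atom:
    """One atom record of a structure file."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    chain_id: str
    residue_name: str
    residue_number: int
    insertion_code: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.serial} ({self.name}) has no element")
        if not all(math.isfinite(c) for c in self.coords):
            raise StructureError(f"atom {self.serial} has non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.residue_name, self.residue_number, self.insertion_code)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell with its space-group operators.

    ``symmetry_ops`` are pairs ``(R, t)`` acting on fractional coordinates,
    ``f' = R f + t``. The identity is always present. Orthogonalization follows
    the standard crystallographic convention: *a* along x, *b* in the x-y plane.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    symmetry_ops: tuple[tuple[tuple, tuple], ...] = (
        (((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)), (0.0, 0.0, 0.0)),
    )
    space_group: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("unit cell lengths must be positive")
        if not all(0 < ang < 180 for ang in (self.alpha, self.beta, self.gamma)):
            raise StructureError("unit cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise StructureError("unit cell volume must be positive")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with xyz = M @ fractional."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orthogonalization_matrix.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.fractionalization_matrix.T

    def operator_arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(np.asarray(r, dtype=float), np.asarray(t, dtype=float)) for r, t in self.symmetry_ops]


@dataclass
class Structure:
    """A set of atoms with optional unit-cell/symmetry information."""

    atoms: list[Atom]
    unit_cell: UnitCell | None = None
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def receptor_atoms(
        self,
        include_hetero: bool = False,
        include_waters: bool = False,
        exclude_residues: Iterable[tuple] = (),
    ) -> list[Atom]:
        """Heavy atoms forming the receptor for grid annotation.

        Default policy: polymer (non-HETATM) atoms only; waters and other
        HETATM are excluded unless the corresponding flag is set. Residues in
        ``exclude_residues`` (keys as :attr:`Atom.residue_key`) are always
        dropped — used to remove a selected ligand from its own receptor.
        """
        excl = set(exclude_residues)
        out = []
        for a in self.atoms:
            if a.is_hydrogen or a.residue_key in excl:
                continue
            if a.is_water and not include_waters:
                continue
            if a.is_hetero and not a.is_water and not include_hetero:
                continue
            out.append(a)
        return out

    def subset(self, atoms: Sequence[Atom], source_suffix: str = "") -> "Structure":
        return Structure(list(atoms), unit_cell=self.unit_cell, source_id=self.source_id + source_suffix)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = [replace(a, coords=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(new_atoms, unit_cell=self.unit_cell, source_id=self.source_id)


@dataclass(frozen=True)
class LigandSelection:
    """The heavy atoms of one selected bound ligand."""

    atoms: tuple[Atom, ...]
    selector: str

    def __post_init__(self) -> None:
        if not self.atoms:
            raise SelectionError(f"ligand selection {self.selector!r} is empty")
        if any(a.is_hydrogen for a in self.atoms):
            raise SelectionError("ligand selection must contain heavy atoms only")
        if len({a.residue_key for a in self.atoms}) != 1:
            raise SelectionError("ligand atoms must share a single residue identity")

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return self.atoms[0].residue_key

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


# ---------------------------------------------------------------------------
# parsing


_ELEMENT_FALLBACK_2 = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE", "CU", "NI", "CO"}


def _infer_element(name: str, residue_name: str) -> str:
    """Heuristic element from the atom name when the element column is absent."""
    stripped = name.strip()
    if not stripped:
        return ""
    up = stripped.upper()
    if up[:2] in _ELEMENT_FALLBACK_2 and residue_name.upper() not in ("CA",):
        # two-letter elements; CA-the-calcium vs CA-the-alpha-carbon is decided
        # by residue context upstream (gemmi normally resolves it for us)
        if up[:2] == "CA" and not residue_name.upper() in ("CA", "ION"):
            return "C"
        return up[:2].capitalize()
    head = up.lstrip("0123456789")
    return head[:1] if head else up[:1]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    Keeps ATOM/HETATM records with blank or 'A' altloc; parses CRYST1 into a
    :class:`UnitCell` when present (symmetry operators looked up from the
    space-group symbol). Waters are retained but flagged by residue name.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    fmt = format.lower()
    if fmt not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    return _from_gemmi(st, source_id=path.stem)


def _from_gemmi(st: "gemmi.Structure", source_id: str) -> Structure:
    atoms: list[Atom] = []
    serial = 0
    model = st[0] if len(st) else None
    if model is None:
        raise StructureError(f"{source_id}: no model in file")
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                serial += 1
                elem = at.element.name if at.element and at.element.name != "X" else ""
                if not elem:
                    elem = _infer_element(at.name, res.name)
                atoms.append(
                    Atom(
                        serial=at.serial if at.serial else serial,
                        name=at.name,
                        element=elem,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        is_hetero=het,
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                    )
                )
    if not atoms:
        raise StructureError(f"{source_id}: zero atoms parsed")
    cell = None
    gc = st.cell
    has_cell = gc is not None and gc.volume > 2.0 and not (
        gc.a == gc.b == gc.c == 1.0 and gc.alpha == gc.beta == gc.gamma == 90.0
    )
    if has_cell:
        hm = st.spacegroup_hm or "P 1"
        ops = _ops_for_space_group(hm)
        cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma,
                        symmetry_ops=ops, space_group=hm)
    return Structure(atoms, unit_cell=cell, source_id=source_id)


def _ops_for_space_group(hm_symbol: str) -> tuple:
    sg = gemmi.find_spacegroup_by_name(hm_symbol)
    if sg is None:
        raise MissingSymmetryError(f"unknown space-group symbol {hm_symbol!r}")
    den = float(gemmi.Op.DEN)
    ops = []
    for op in sg.operations():
        rot = tuple(tuple(x / den for x in row) for row in op.rot)
        tran = tuple(x / den for x in op.tran)
        ops.append((rot, tran))
    return tuple(ops)


# ---------------------------------------------------------------------------
# writing


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a fixed-column PDB file (CRYST1 + ATOM/HETATM)."""
    path = Path(path)
    lines = []
    cell = structure.unit_cell
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {cell.space_group:<11s}{1:4d}"
        )
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        serial = i if i <= 99999 else 99999
        resnum = a.residue_number if -999 <= a.residue_number <= 9999 else 9999
        x, y, z = a.coords
        lines.append(
            f"{record}{serial:5d} {name:<4s} {a.residue_name:<3s} "
            f"{(a.chain_id or 'A')[:1]}{resnum:4d}{(a.insertion_code or ' ')[:1]}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections


def select_chains(structure: Structure, chain_ids: Iterable[str]) -> Structure:
    """Restrict a structure to the given chain identifiers (unit cell preserved)."""
    wanted = set(chain_ids)
    if not wanted:
        raise SelectionError("chain selection is empty")
    atoms = [a for a in structure.atoms if a.chain_id in wanted]
    if not atoms:
        present = ",".join(sorted(structure.chain_ids))
        raise SelectionError(
            f"no atoms in chains {sorted(wanted)}; structure has chains [{present}]"
        )
    return structure.subset(atoms)


def extract_ligand(structure: Structure, selector: str) -> LigandSelection:
    """Extract the heavy atoms of one residue given a ``RESNAME:CHAIN:RESNUM`` selector."""
    parts = selector.split(":")
    if len(parts) != 3:
        raise SelectionError(f"ligand selector {selector!r} must be RESNAME:CHAIN:RESNUM")
    resname, chain, resnum_s = parts
    try:
        resnum = int(resnum_s)
    except ValueError:
        raise SelectionError(f"residue number in {selector!r} is not an integer") from None
    groups: dict[tuple, list[Atom]] = {}
    for a in structure.atoms:
        if (
            a.residue_name.upper() == resname.upper()
            and a.chain_id == chain
            and a.residue_number == resnum
        ):
            groups.setdefault(a.residue_key, []).append(a)
    if not groups:
        raise SelectionError(f"no residue matches ligand selector {selector!r}")
    if len(groups) > 1:
        raise SelectionError(f"ligand selector {selector!r} is ambiguous ({len(groups)} residues)")
    (atoms,) = groups.values()
    heavy = tuple(a for a in atoms if not a.is_hydrogen)
    if not heavy:
        raise SelectionError(f"residue {selector!r} has no heavy atoms")
    return LigandSelection(atoms=heavy, selector=selector)


def parse_symmetry(structure: Structure) -> UnitCell:
    """Return the structure's unit cell with a complete symmetry-operator list.

    Fatal for channel analysis when the file had no CRYST1 record.
    """
    if structure.unit_cell is None:
        raise MissingSymmetryError(
            f"structure {structure.source_id!r} has no CRYST1 unit cell; "
            "crystal channel analysis needs cell parameters and a space group"
        )
    return structure.unit_cell
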