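"""Synthetic test structures with known cavity and channel geometry.

Pseudo-atoms (carbon, vdW 1.7 Å) are placed on a cubic lattice dense enough
(1.2 Å) that walls are solid at the grid spacings used for detection. All void
radii are *solvent* radii: atom centers are kept at least ``radius + r_C``
away from the void axis/center, so a "radius 5 cavity" really admits a 5 Å
probe and has the analytic solvent volume 4/3 π 5³.

Every generator is deterministic for a given seed (the seed only matters when
a jitter amplitude is requested) and emits structures that round-trip through
the PDB writer/reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure, UnitCell, vdw_radius

__all__ = [
    "FixtureSpec",
    "ATOM_SPACING",
    "CARBON_RADIUS",
    "make_hollow_shell",
    "make_shallow_groove",
    "make_tube_crystal",
    "make_neck_chamber",
]

#: lattice constant of the pseudo-atom packing (Å); 1.2 < 2*1.7/sqrt(3), so
#: nearest-neighbour vdW spheres overlap along all lattice directions
ATOM_SPACING = 1.2
CARBON_RADIUS = vdw_radius("C")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture (used by the CLI)."""

    kind: str  # hollow_shell | shallow_groove | tube_crystal | neck_chamber
    params: dict = field(default_factory=dict)
    seed: int = 0

    def build(self) -> Structure:
        builders = {
            "hollow_shell": make_hollow_shell,
            "shallow_groove": make_shallow_groove,
            "tube_crystal": make_tube_crystal,
            "neck_chamber": make_neck_chamber,
        }
        if self.kind not in builders:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        return builders[self.kind](seed=self.seed, **self.params)


#: spacing of wall-lining surface points (Å); keeps the discrete void boundary
#: within ~0.1 Å of the nominal analytic radius
LINING_SPACING = 0.8
_LINING_EPS = 0.15


def _lattice(lo: np.ndarray, hi: np.ndarray, spacing: float) -> np.ndarray:
    axes = [np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _sphere_surface(center: np.ndarray, radius: float, spacing: float = LINING_SPACING) -> np.ndarray:
    """Near-uniform (Fibonacci) point layer on a sphere."""
    n = max(8, int(np.ceil(4.0 * np.pi * radius**2 / spacing**2)))
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = radius * np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return pts + center


def _cylinder_surface(
    a: np.ndarray, b: np.ndarray, radius: float, spacing: float = LINING_SPACING
) -> np.ndarray:
    """Point layer on the lateral surface of the cylinder around segment a-b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    axis = b - a
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    n_ang = max(6, int(np.ceil(2.0 * np.pi * radius / spacing)))
    n_len = max(2, int(np.ceil(length / spacing)) + 1)
    ts = np.linspace(0.0, length, n_len)
    angs = 2.0 * np.pi * np.arange(n_ang) / n_ang
    ring = radius * (np.cos(angs)[:, None] * u + np.sin(angs)[:, None] * v)
    pts = (a[None, None, :] + ts[:, None, None] * axis[None, None, :] + ring[None, :, :])
    return pts.reshape(-1, 3)


def _carbon_atoms(points: np.ndarray, rng: np.random.Generator | None, jitter: float) -> list[Atom]:
    if jitter > 0 and rng is not None:
        points = points + rng.uniform(-jitter, jitter, size=points.shape)
    atoms = []
    for i, p in enumerate(points):
        atoms.append(
            Atom(
                serial=i + 1,
                name="C",
                element="C",
                coords=tuple(np.round(p, 3)),
                chain_id="A",
                residue_name="DUM",
                residue_number=(i % 9999) + 1,
            )
        )
    return atoms


def _marker_ligand(center: np.ndarray, start_serial: int) -> list[Atom]:
    """Three-carbon HETATM marker residue LIG (chain L, residue 1)."""
    offsets = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [-1.4, 0.0, 0.0]])
    return [
        Atom(
            serial=start_serial + i,
            name=f"C{i + 1}",
            element="C",
            coords=tuple(np.round(center + off, 3)),
            chain_id="L",
            residue_name="LIG",
            residue_number=1,
            is_hetero=True,
        )
        for i, off in enumerate(offsets)
    ]


def make_hollow_shell(
    cavity_radius: float = 5.0,
    shell_thickness: float = 3.0,
    mouth_radius: float = 2.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Spherical solvent cavity of the given radius inside a solid shell,
    opened by a cylindrical mouth of the given solvent radius along +z.

    The cavity center is at the origin. Atom centers fill the radial range
    [cavity_radius + r_C, cavity_radius + r_C + shell_thickness].
    """
    if cavity_radius <= 0 or shell_thickness <= 0:
        raise ValueError("cavity radius and shell thickness must be positive")
    if not 0 < mouth_radius < cavity_radius:
        raise ValueError("mouth radius must lie in (0, cavity_radius)")
    inner = cavity_radius + CARBON_RADIUS
    outer = inner + shell_thickness
    mouth_wall = mouth_radius + CARBON_RADIUS
    pts = _lattice(np.full(3, -outer), np.full(3, outer), ATOM_SPACING)
    r = np.linalg.norm(pts, axis=1)
    keep = (r >= inner) & (r <= outer)
    # carve the mouth: along +z, remove wall atoms near the axis so that the
    # remaining solvent passage has radius ~= mouth_radius
    rho = np.linalg.norm(pts[:, :2], axis=1)
    keep &= ~((pts[:, 2] > 0) & (rho < mouth_wall))
    pts = pts[keep]
    # line the cavity wall and the mouth wall with dense surface layers so the
    # discrete solvent boundary sits at the nominal radii
    cav_lining = _sphere_surface(np.zeros(3), inner)
    lin_rho = np.linalg.norm(cav_lining[:, :2], axis=1)
    cav_lining = cav_lining[~((cav_lining[:, 2] > 0) & (lin_rho < mouth_wall - _LINING_EPS))]
    z_int = np.sqrt(max(inner**2 - mouth_wall**2, 0.0))
    mouth_lining = _cylinder_surface(
        np.array([0.0, 0.0, z_int - 0.4]), np.array([0.0, 0.0, outer]), mouth_wall
    )
    mouth_lining = mouth_lining[np.linalg.norm(mouth_lining, axis=1) > inner - _LINING_EPS]
    pts = np.vstack([pts, cav_lining, mouth_lining])
    rng = np.random.default_rng(seed)
    atoms = _carbon_atoms(pts, rng, jitter)
    return Structure(atoms, source_id="hollow_shell")


def make_shallow_groove(
    groove_radius: float = 3.0,
    groove_depth: float = 1.2,
    slab_half_extent: float = 9.0,
    slab_thickness: float = 4.8,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Flat slab with a shallow open dimple and a marker ligand hovering in it.

    The groove is open to bulk solvent from above, so it is flanked by the
    macromolecule only along the two in-plane axes — by design too exposed to
    seed a pocket without ligand bias.
    """
    if groove_radius <= 0 or groove_depth <= 0:
        raise ValueError("groove radius and depth must be positive")
    if groove_radius >= slab_half_extent:
        raise ValueError("groove must be smaller than the slab")
    lo = np.array([-slab_half_extent, -slab_half_extent, -slab_thickness])
    hi = np.array([slab_half_extent, slab_half_extent, 0.0])
    pts = _lattice(lo, hi, ATOM_SPACING)
    rho = np.linalg.norm(pts[:, :2], axis=1)
    keep = ~((rho < groove_radius) & (pts[:, 2] > -groove_depth))
    rng = np.random.default_rng(seed)
    atoms = _carbon_atoms(pts[keep], rng, jitter)
    lig_center = np.array([0.0, 0.0, CARBON_RADIUS - groove_depth + 0.8])
    atoms += _marker_ligand(lig_center, start_serial=len(atoms) + 1)
    return Structure(atoms, source_id="shallow_groove")


def _p1_cell(edge: float) -> UnitCell:
    return UnitCell(edge, edge, edge, 90.0, 90.0, 90.0, space_group="P 1")


def make_tube_crystal(
    tube_radius: float = 4.0,
    cell_edge: float = 20.0,
    constriction_radius: float | None = None,
    constriction_half_width: float = 1.2,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Cubic P1 cell densely filled with atoms except a cylindrical solvent
    channel of the given radius along c (axis through the cell center).

    With ``constriction_radius`` set, a ring narrowing the channel to that
    radius is inserted at mid-height, making it the widest-path bottleneck.
    """
    if tube_radius < 0:
        raise ValueError("tube radius must be >= 0")
    if cell_edge <= 0:
        raise ValueError("cell edge must be positive")
    if tube_radius > 0 and tube_radius + CARBON_RADIUS + 0.6 > cell_edge / 2:
        raise ValueError("tube does not fit in the cell with solid walls")
    if constriction_radius is not None and constriction_radius > tube_radius:
        raise ValueError("constriction radius must not exceed the tube radius")
    half = cell_edge / 2.0
    # fill [0, cell_edge) so that wrapped copies tile seamlessly
    pts = _lattice(np.zeros(3), np.full(3, cell_edge - 0.5 * ATOM_SPACING), ATOM_SPACING)
    if tube_radius > 0:
        tube_wall = tube_radius + CARBON_RADIUS
        rho = np.linalg.norm(pts[:, :2] - half, axis=1)
        carve = rho <= tube_wall
        if constriction_radius is not None:
            in_ring = np.abs(pts[:, 2] - half) <= constriction_half_width
            carve &= ~(in_ring & (rho > constriction_radius + CARBON_RADIUS))
        pts = pts[~carve]
        axis_lo = np.array([half, half, 0.0])
        axis_hi = np.array([half, half, cell_edge])
        lining = _cylinder_surface(axis_lo, axis_hi, tube_wall)
        lining = lining[lining[:, 2] < cell_edge - 1e-6]  # avoid periodic duplicates
        if constriction_radius is not None:
            ring_wall = constriction_radius + CARBON_RADIUS
            keep = ~(np.abs(lining[:, 2] - half) <= constriction_half_width - _LINING_EPS)
            lining = lining[keep]
            ring = _cylinder_surface(
                np.array([half, half, half - constriction_half_width]),
                np.array([half, half, half + constriction_half_width]),
                ring_wall,
            )
            lining = np.vstack([lining, ring])
        pts = np.vstack([pts, lining])
    rng = np.random.default_rng(seed)
    atoms = _carbon_atoms(pts, rng, jitter)
    return Structure(atoms, unit_cell=_p1_cell(cell_edge), source_id="tube_crystal")


def make_neck_chamber(
    chamber_radius: float = 5.0,
    neck_radius: float = 2.0,
    channel_radius: float = 5.0,
    cell_edge: float = 24.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> Structure:
    """Periodic channel plus a dead-end chamber behind a narrow neck (P1).

    The channel runs along c through the cell corner; the chamber sits on the
    corner diagonal, connected to the channel by a neck of the given solvent
    radius; a three-atom marker ligand (LIG:L:1) floats at the chamber center.
    The largest probe able to reach the ligand is therefore the neck radius,
    while probes up to the channel radius pass in front of the site.
    """
    if chamber_radius <= 0 or channel_radius <= 0:
        raise ValueError("chamber and channel radii must be positive")
    if neck_radius < 0 or neck_radius > min(chamber_radius, channel_radius):
        raise ValueError("need 0 <= neck_radius <= min(chamber_radius, channel_radius)")
    wall = 0.75
    dist_axis = channel_radius + chamber_radius + 2 * CARBON_RADIUS + wall
    half = cell_edge / 2.0
    center = np.array([dist_axis / np.sqrt(2.0), dist_axis / np.sqrt(2.0), half])
    # the chamber must keep solid walls to the cell faces and the channel images
    if center[0] + chamber_radius + CARBON_RADIUS + wall > cell_edge:
        raise ValueError("cell too small for this chamber/channel combination")
    for corner in ([cell_edge, 0.0], [0.0, cell_edge], [cell_edge, cell_edge]):
        if np.linalg.norm(center[:2] - corner) < dist_axis:
            raise ValueError("chamber would open into a periodic channel image")
    channel_wall = channel_radius + CARBON_RADIUS
    chamber_wall = chamber_radius + CARBON_RADIUS
    neck_wall = neck_radius + CARBON_RADIUS
    neck_a = np.array([0.0, 0.0, half])  # on the channel axis
    neck_ab = center - neck_a

    def d_channel(p: np.ndarray) -> np.ndarray:
        # periodic xy distance to the corner axis (which tiles all four corners)
        dxy = p[:, :2] - cell_edge * np.round(p[:, :2] / cell_edge)
        return np.linalg.norm(dxy, axis=1)

    def d_chamber(p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(p - center, axis=1)

    def d_neck(p: np.ndarray) -> np.ndarray:
        t = np.clip((p - neck_a) @ neck_ab / (neck_ab @ neck_ab), 0.0, 1.0)
        return np.linalg.norm(p - (neck_a + t[:, None] * neck_ab), axis=1)

    pts = _lattice(np.zeros(3), np.full(3, cell_edge - 0.5 * ATOM_SPACING), ATOM_SPACING)
    carve = d_channel(pts) <= channel_wall
    carve |= d_chamber(pts) <= chamber_wall
    if neck_radius > 0:
        carve |= d_neck(pts) <= neck_wall
    pts = pts[~carve]
    # wall linings at the exact nominal void boundaries, each trimmed where it
    # falls inside another void
    ch_lining = _cylinder_surface(
        np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, cell_edge]), channel_wall
    )
    ch_lining = ch_lining[ch_lining[:, 2] < cell_edge - 1e-6]
    cb_lining = _sphere_surface(center, chamber_wall)
    linings = [ch_lining, cb_lining]
    if neck_radius > 0:
        linings.append(_cylinder_surface(neck_a, center, neck_wall))
    kept = []
    for lin in linings:
        ok = (
            (d_channel(lin) > channel_wall - _LINING_EPS)
            & (d_chamber(lin) > chamber_wall - _LINING_EPS)
        )
        if neck_radius > 0:
            ok &= d_neck(lin) > neck_wall - _LINING_EPS
        kept.append(lin[ok])
    pts = np.vstack([pts] + kept)
    rng = np.random.default_rng(seed)
    atoms = _carbon_atoms(pts, rng, jitter)
    atoms += _marker_ligand(center, start_serial=len(atoms) + 1)
    return Structure(atoms, unit_cell=_p1_cell(cell_edge), source_id="neck_chamber")
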