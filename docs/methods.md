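# Methods

This note records the models, parameter choices and numerical conventions of
cavgrid, including the decisions made where the design was genuinely open,
and what the synthetic validation structures do and do not demonstrate.

## Input model

Structures are reduced to heavy atoms with element-typed van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, default 1.70 Å). Alternate
locations keep only the blank/'A' conformer, so grids are built from a single
deterministic conformer. Hydrogens are parsed but ignored by every geometric
computation — both engines are heavy-atom methods. Waters are excluded from
the receptor/blocker set by default (crystallographic water should not block
a pocket or a channel probe); other HETATM groups are excluded from the
pocket receptor but *included* as channel blockers by default, and a selected
reference ligand is always removed from its own receptor. All of these are
flags.

## Pocket detection

### Grid and orientation

Pockets use an isotropic cubic grid, default spacing 0.5 Å (sub-Å sampling of
pocket shapes) with 3 Å padding (room for mouths and dilation). Before
gridding, the receptor is rotated into its principal-axes frame: covariance
eigenvectors become the lattice axes, largest variance first. This minimises
the grid and makes detection orientation-invariant. Axis signs follow the
sign of the third central moment along each axis; ties fall back to the
dominant eigenvector component, and the determinant is forced to +1 by
flipping the least-committed axis. Voxel coordinates are mapped back through
the inverse transform whenever results are reported, so users always see the
input frame.

### Occupancy

A voxel is MACROMOLECULE iff its distance to the nearest heavy-atom centre is
at most that atom's vdW radius plus a solvent margin (default 0 Å; a knob for
users who want a probe-inflated surface). Everything else is SOLVENT.

### DoG response

The solvent indicator (SOLVENT = 1) is blurred with two Gaussians,
σ₁ = 0.8 Å and σ₂ = 2.4 Å (a 1:3 ratio placing the blob scale near a small
substituent), and the difference taken. Outside the grid the indicator is
continued by edge padding, so a uniform field maps to exactly zero and grid
boundaries do not ring.

The seed threshold is *auto-calibrated*: it is a fraction (default 0.25) of
the peak DoG response of an isolated 3 Å spherical cavity computed at the
current spacing and sigmas. This makes the threshold resolution-independent.
The fraction is deliberately low. The DoG response of a cavity *shrinks* as
its radius grows past σ₂ — in the flat-wall limit the best achievable
response is only about one third of the 3 Å reference — so a high fraction
would reject exactly the large, well-formed cavities the detector exists to
find. Setting the fraction at 0.25 admits buried cavities of any radius from
roughly 1 Å upward and delegates buriedness discrimination to the PSP gate.

### PSP events

For each of seven scan directions (three axes, four body diagonals) a solvent
voxel scores one event when macromolecule voxels exist on both sides along
that line within the grid; the grid edge counts as open (bulk solvent).
Macromolecule voxels score zero. The default seed gate is a count ≥ 3: an
open planar groove is flanked only along the two in-plane axes (count 2),
while genuinely enclosed cavities reach 6–7, so 3 is the smallest gate that
separates the two regimes. This is also what makes the ligand-bias mode
meaningful: shallow sites fail the gate until their voxels are promoted.

### Clustering, dilation, filtering

Seeds are clustered under 26-connectivity (we want a cavity sampled at
sub-voxel offsets to stay one object). Each cluster is grown by a Euclidean
dilation of 1 Å into solvent only; clusters whose grown sets intersect merge
(transitive closure), giving a well-defined partition. Finally pockets with
V < 20 Å³ are removed — strictly: a pocket of exactly 20 Å³ is retained —
with V = voxel count × spacing³. Filtering happens after merging. Pockets are
ranked by descending volume, ties broken by smallest flat voxel index for
determinism.

### Ligand bias

Voxels within 2.5 Å of a chosen ligand's heavy atoms get their DoG value
raised to the seed threshold and their PSP count floored at the gate; nothing
else changes. Promotion is monotone — enabling bias can only add seeds — and
seeds remain solvent-only because clustering intersects with the solvent
mask. 2.5 Å covers the first solvation shell of the ligand without leaking
into bulk.

### Descriptors

All descriptors are voxel-set based: volume as above; surface as exposed
voxel faces × spacing² (a voxelized surface overestimates a smooth one by up
to ~1.5×, which is documented rather than corrected); depth as the maximum
distance from a pocket voxel to the nearest *mouth* voxel (a pocket voxel
with a 6-neighbour that is solvent but not pocket), falling back to half the
maximum pairwise extent for fully enclosed pockets; lining residues as those
with a heavy atom within 4 Å of a voxel centre. Ligand coverage and pocket
coverage are volumetric: with L the solvent voxels within the vdW radius of
any ligand heavy atom and P the pocket, coverage = |L∩P|/|L| and |L∩P|/|P|.

## Solvent channels

### Cell expansion and clearance

The asymmetric unit is replicated by the space-group operators (looked up
from the Hermann–Mauguin symbol), wrapped into [0,1)³, and images of the same
atom closer than 0.3 Å (special positions) collapse to one copy. The cell
grid uses integer subdivisions of each cell edge near a 0.8 Å target, at
least 16 per axis. Clearance at a voxel is the minimum over atoms (atoms
wrapped into the cell, replicated in the 26 neighbouring cells) of distance
minus vdW radius, clamped to [0, cap] with cap = half the shortest cell edge;
given the cap, 27 images suffice for minimum-image correctness. The probe is
a hard sphere against vdW spheres — no solvent-probe rolling.

### Local bottleneck radii

Voxels are activated in order of decreasing clearance and joined to active
6-connected periodic neighbours with an offset-tracking union-find: every
node stores its integer lattice offset relative to its component root, and a
union that closes a cycle with non-zero net offset proves the component
connects to its own lattice translate — an infinite periodic path. A voxel's
local bottleneck radius is the sweep level at which it first belongs to a
percolating component (0 if never), which equals the clearance of the
narrowest constriction on the widest path reaching it. The sweep is exact
(verified voxel-for-voxel against a threshold-and-BFS search on random
periodic grids); percolation along *any* lattice direction counts.
6-connectivity is deliberate and conservative: a sphere must pass through
face-adjacent voxels, and diagonal adjacency would overestimate passable
width. The price is a discretization penalty of up to about two grid steps on
paths running diagonally to the lattice (one step of static voxel-centre
offset plus one step of staircase detour), versus about one step for
axis-aligned channels; tolerances on fixture checks reflect this.

### Site radii

With a reference ligand, the *inner* active-site radius is the maximum local
bottleneck radius over periodic voxels within 3 Å of a ligand heavy atom —
the largest probe that can actually reach the ligand position. The *outer*
radius is the maximum over voxels within a 5 Å shell outside the mouth of
the ligand's pocket (the detected pocket with the highest ligand coverage) —
the largest probe that passes directly in front of the site. The inner
radius is referenced to the ligand region rather than the whole pocket
because dilation/merging can legitimately fuse a site with an adjoining
channel, and the question the number answers is "what can reach the ligand",
not "what fits anywhere in the fused pocket". Both radii are 0 when no
percolating path reaches the region; they are absent when no ligand is
given. The 5 Å mouth shell and the 3 Å ligand region are this package's
operationalizations of "in front of" and "inside" the pocket.

## Synthetic validation structures

The fixtures place carbon pseudo-atoms (vdW 1.7 Å) on a 1.2 Å cubic lattice —
dense enough that nearest-neighbour spheres overlap along every lattice
direction, so walls are solid at the 0.5–0.8 Å analysis grids. All void radii
are *solvent* radii: atom centres are kept at `radius + 1.7 Å` from the void
axis or centre, and each void wall is additionally lined with a ~0.8 Å-spaced
surface layer of atom centres at exactly that distance, pinning the discrete
solvent boundary to the nominal radius (a bare lattice cut lets solvent creep
~0.5–1 Å between atoms, inflating cavity volumes by tens of percent).

* `hollow_shell` — spherical cavity (default 5 Å) in a 3 Å shell with a 2 Å
  cylindrical mouth: known centre and analytic volume 4/3·π·r³.
* `shallow_groove` — a slab with an open dimple and a hovering marker
  ligand: constructed to fail the PSP gate (count 2) so that only ligand-bias
  mode detects it.
* `tube_crystal` — P1 cube with a cylindrical channel (optionally narrowed by
  a constriction ring): known overall bottleneck.
* `neck_chamber` — P1 cell with a corner channel, a dead-end chamber on the
  corner diagonal, and a neck of chosen radius between them: known inner
  (neck) and outer (channel) site radii. The channel axis distance is chosen
  so chamber and channel images never open into each other.

What passing these tests shows: the grid machinery, the DoG/PSP gates, the
percolation sweep and the descriptor arithmetic recover known geometry to
grid precision, and detection is invariant under rigid motion and lattice
translation. What they do not show: performance of the default thresholds on
real protein surfaces (rough, chemically heterogeneous, with partial
occupancy and waters), agreement with any particular published tool's pocket
boundaries, or soaking behaviour beyond hard-sphere geometry (no
electrostatics, flexibility, or solvent dynamics). One test each checks a
printed reference value on a real PDB entry (pocket count on 8g66 chain C;
11 Å channel percolation in 5seq); these fetch the entries at run time and
require network access.

## Numerical conventions and sizes

* Orthogonalization follows the crystallographic standard: *a* along x, *b*
  in the x–y plane; fractional↔orthogonal transforms derive from the cell.
* CCP4 maps are MRC2014-compatible, mode 2 float32, axis order X,Y,Z; the
  grid origin is stored in the MRC origin words, and write→read round trips
  are lossless at float32.
* Problem sizes used by the test suite and the acceptance script: oracle
  comparisons run on 9³ label grids and ≤ 8³ periodic grids (sizes where the
  brute-force references are exact and fast); fixture analyses run at the
  default 0.5 Å / 0.8 Å spacings on 20–24 Å structures, i.e. ~10⁵–10⁶ voxel
  grids — the same code paths as production runs, at moderate extents.
* Degenerate inputs: empty structures, collinear point sets, selectors
  matching zero or several residues, missing CRYST1 in channels mode, and
  ligands outside the grid all raise typed, actionable errors.

## Known limitations

* No druggability or chemical scoring — the detectors are purely geometric.
* No sub-pocket decomposition.
* Pocket-boundary details (and hence descriptor values) depend on the seed
  thresholds; the defaults were chosen by the geometric arguments above, not
  fitted to any benchmark.
* The channel probe ignores B-factors, occupancy and non-crystallographic
  symmetry; anisotropic cells are supported but the pocket grid is always
  isotropic.
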