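# cavgrid

Grid-based geometry engines for two everyday questions in structure-based
drug design:

1. **Where are the binding pockets?** `cavgrid.pockets` detects ligand
   binding sites on protein and nucleic-acid structures from pure geometry —
   no energy model, no training data — and computes per-pocket descriptors
   (volume, surface, depth, lining residues, ligand/pocket coverage).
2. **Can a compound soak into this crystal?** `cavgrid.channels` analyses the
   periodic solvent channels of a crystal structure and reports the *bottleneck
   radius*: the largest spherical probe that can percolate through the crystal
   lattice, and the largest probe that can reach a chosen binding site.

It is a library plus a thin `cavgrid` command-line tool, reading PDB (and
mmCIF) structures and writing CCP4/MRC maps, PDB pocket models, and TSV/JSON
summaries.

## Methods in brief

**Pocket detection.** The structure is rotated into its principal-axes frame
(PCA; makes the result orientation-invariant and the grid minimal) and mapped
onto a cubic voxel grid (default 0.5 Å). Each voxel is labelled MACROMOLECULE
if it lies within the van der Waals radius of a heavy atom, else SOLVENT. Two
per-voxel signals gate pocket seeds:

* the **Difference-of-Gaussian (DoG)** response of the solvent indicator
  field, `G_{σ1} * s − G_{σ2} * s` with σ₁ = 0.8 Å, σ₂ = 2.4 Å, which peaks
  in sphere-like solvent cavities; and
* the **protein–solvent–protein (PSP) event count**: along the three lattice
  axes and the four cube-corner diagonals, a solvent voxel scores one event
  per direction in which macromolecule lies on *both* sides. The count in
  [0, 7] measures buriedness (an open groove scores 2, an enclosed cavity
  6–7).

Seed voxels (DoG above an auto-calibrated threshold, PSP ≥ 3) are clustered
into connected components, grown by a 1 Å dilation radius, merged, and
pockets with V < 20 Å³ are removed. An optional **ligand-bias mode** promotes
voxels near a chosen ligand to guaranteed seeds, recovering shallow,
hard-to-detect sites that cover the ligand volume.

**Solvent channels.** The asymmetric unit is expanded by the space-group
operators into one full unit cell. On a periodic grid (default 0.8 Å) the
*clearance* field is computed (distance to the nearest vdW sphere, minimum
image). A union-find sweep in order of decreasing clearance — tracking the
lattice offset of every voxel relative to its component root — converts
clearance into the **local bottleneck radius**: a component that closes a
cycle with non-zero net lattice offset touches its own translate, i.e. forms
an infinite periodic path, and every voxel joining such a component is
reachable by a probe of the current sweep radius. The field's maximum is the
**overall bottleneck radius**; with a reference ligand, the **inner/outer
active-site radii** report the bottleneck inside and in front of its pocket.

## Worked example

Generate a synthetic crystal — a 24 Å P1 cell with a 5 Å solvent channel and
a dead-end chamber connected through a 2 Å neck, with a marker ligand in the
chamber — and ask whether a soaking compound could reach the ligand site:

```bash
cavgrid fixtures neck_chamber --out neck.pdb
cavgrid channels neck.pdb --ligand LIG:L:1 --out chan
cat chan/channels.json
```

```json
{
  "grid_shape": [30, 30, 30],
  "grid_spacing_A": 0.8,
  "inner_site_radius_A": 1.4388,
  "outer_site_radius_A": 4.931,
  "overall_bottleneck_A": 4.931
}
```

Probes of radius ≈ 4.9 Å percolate through the crystal and pass directly in
front of the site (outer radius), but only probes smaller than ≈ 1.4–2 Å can
squeeze through the neck into the chamber itself (inner radius; the nominal
neck radius is 2 Å, measured on a 0.8 Å grid). `chan/channels.ccp4` holds the
local-bottleneck field: thresholding it at radius r in any viewer shows
exactly the space reachable by a probe of that size.

Pocket detection on a hollow-shell test structure (5 Å spherical cavity,
2 Å mouth):

```bash
cavgrid fixtures hollow_shell --out shell.pdb
cavgrid pockets shell.pdb --out pk
cat pk/pockets.tsv
```

```text
pocket_id  volume_A3  surface_A2  depth_A  n_voxels  centroid_x  centroid_y  centroid_z  ...
1          610.875    589.5       14.654   4887      0.001       -0.011      0.993       ...
```

One pocket is found, centred on the cavity (centroid within 1 Å of the true
centre) with a volume within 17% of the analytic 523.6 Å³; per-pocket PDB
pseudo-atom models and CCP4 masks are written alongside the table.

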