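# Methods

## Coordinate model and conventions

All geometry operates on an ordered list of atom records (chain, residue
number + insertion code, residue name, atom name, element, Å position,
altloc, HETATM flag) parsed from PDB or mmCIF via gemmi. Coordinates are in
Å with right-handed axes; z is the membrane normal with the extracellular
side at larger z (OPM convention). Residue numbering is kept as deposited.
Only altlocs blank/"A" are read, giving a deterministic single-conformer
model. Hydrogens are retained at parse time (flagged by element) but
excluded from every downstream geometric computation, because deposited
receptor models lack them; this also means polar contacts are judged by
distance only, with no donor–acceptor angle term — a known limitation.

## Membrane-frame placement

A receptor is placed in the membrane frame by proper-rotation Kabsch
superposition of its Cα trace onto a user-supplied, already
membrane-aligned reference, paired by (chain, residue number, insertion
code). Pairing is restricted to TM-annotated residues by default since
loops differ between activation states; `pairing="all"` uses every common
Cα. If the optimal orthogonal matrix has determinant −1 the smallest
singular vector's sign is flipped. Collinear point sets are rejected
(rotation about the line is undetermined). The package deliberately does
not bundle reference coordinates nor re-implement implicit-membrane
optimization; any membrane-aligned structure serves as reference.

## Cavity boundaries

The lateral boundary at a given z is the closed polygon through the TM
helix centers at that z. A helix center is the mean (x, y) of the helix's
Cα atoms within |z_atom − z| ≤ w; when the window is empty (beyond the
helix ends) the (x, y) of the Cα nearest in z is used, with ties broken
toward the lower residue number. The polygon visits helices in id order
TM1→…→TM7→TM1 (GPCR helices are arranged sequentially around the bundle);
an angular sort is available for annotations whose index order is not
circular. Polygons may be non-convex; no convex hull or smoothing is
applied, and the point-in-polygon test (even–odd ray casting, points on an
edge counted inside) handles non-convex rings.

The window default is w = 2.0 Å. On an ideal α-helix (1.5 Å rise, 100°
twist, 2.3 Å Cα radius) a ±2 Å window holds only ~3 Cα — roughly 270° of
the helical wheel — so individual centers sit up to ~0.5 Å off the true
axis. The bias direction rotates with z, so volumes, which integrate many
slabs, are nearly unaffected (the analytic-prism recovery below is <1%
off), but callers wanting accurate *individual* centers should widen the
window to ≥ 5.25 Å (≥ 7 Cα at any z offset, error < 0.1 Å). The default
follows the slab-local definition of the boundary; tests that assert
per-center accuracy pass the wider window explicitly.

The vertical bounds are z_lower = z of the toggle-switch (6.48) Cα and
z_upper = the maximum z over Cα atoms of all TM-annotated residues, both
Cα-based for consistency. "Most extracellular TM residue" is read as the
global maximum over helices; per-helix alternatives (min or mean of helix
tops) were considered and not adopted. Equal bounds denote a degenerate
empty slab (volume 0); inverted bounds (toggle above the TM tops) are a
geometry error.

## Grid volume

The grid covers the receptor's bounding box at spacing h (default 0.5 Å),
origin snapped to multiples of h so results are deterministic for a given
input. A point is retained iff it lies in the closed interval
[z_lower, z_upper], inside the lateral polygon of its own z level, and no
receptor heavy atom lies within (vdW radius + probe radius) of it. Volume
is exactly N·h³. Clash radii come from a named table: "bondi" (Bondi vdW
radii, 1.70 Å for unlisted elements) or "zero" (all zero — disables clash
removal, isolating the boundary geometry; used by the analytic-prism
checks, since helix atoms always straddle the polygon corners and no
physical bundle has a clash-free boundary). Custom tables can be
registered. The probe radius defaults to 0 (clash with the bare atom); 1.4
Å approximates a water probe.

Known discretization behavior: counting closed-interval z levels adds about
one slab (h / height relative bias, ~1% at h = 0.25 Å on the synthetic
bundle), and lateral edges contribute ±h²·perimeter-scale fluctuation.
Halving the spacing from 0.5 to 0.25 Å changes synthetic-bundle volumes by
under 5%, which justifies 0.5 Å as the default; both the spacing and all
tolerances above are configuration, not fit parameters.

Receptor selection: hydrogens are always dropped; an exclude selector
removes non-receptor atoms (bound peptide agonist, G protein, antibody
fragments, small-molecule ligands, waters, ions) before clash testing.
Without this, an agonist-bound pocket would be occluded by its own ligand —
the quantity of interest is a property of the receptor conformation.

## Monte-Carlo oracle

The independent check on the grid enumeration samples points uniformly in
the bounding box of the boundary region and applies the identical three
retention predicates (each sample is assigned the polygon of its nearest
grid z level). Volume = box volume × acceptance fraction, with a binomial
standard error. Grid and oracle agree within 3 SE plus the discretization
bound h²·(boundary area) on seeded random bundles; this is asserted in the
acceptance suite over five bundles with randomized radii and per-helix
tilts.

## Activation geometry

*Displacements.* State B is superposed onto state A using common Cα atoms
of a configurable alignment selection (default: all common TM residues),
then per-residue Cα distances are reported. The "extracellular tip" of a
helix is its largest-z modeled residue within the annotated range. When a
single helix's motion is measured on synthetic pairs, the alignment
excludes the moving helix so that the applied displacement is recovered
exactly; with whole-TM alignment part of the motion is absorbed into the
fit, which is the same trade-off faced when comparing deposited state
pairs.

*Helix axes and tilts.* The axis is the largest-variance principal
component of the centered Cα trace (≥5 points), signed toward increasing
residue number; tilt between two axes is arccos|a·b| in degrees — unsigned
and acute by convention, so antiparallel axes tilt by 0°. PCA on an ideal
helix is exactly axial only when the Cα set covers whole wheel periods (18
residues at 100°/residue); fractional turns bias the axis by ~1°, which is
below the effect sizes of interest here.

*Rotamers.* χ1 is the N–CA–CB–γ torsion (IUPAC sign, cis = 0°), with the γ
atom per residue type (OG/OG1/SG/CG1/CG). Classes are the canonical wells:
trans 180°±60°, gauche+ −60°±60°, gauche− +60°±60°, with half-open
boundaries at ±120° and 0° for determinism. Gly/Ala are undefined; missing
atoms yield "undefined" with a warning rather than an exception, so a scan
over a whole chain never aborts.

*Contacts.* Distance-only cutoffs: polar N/O/S–N/O/S ≤ 3.5 Å; any heavy
pair ≤ 4.0 Å (van der Waals); Arg/Lys/His sidechain N vs Asp/Glu sidechain
O or a C-terminal carboxylate (O/OXT) ≤ 4.0 Å (salt bridge); Arg/Lys cation
atoms within 6.0 Å of a Phe/Tyr/Trp six-membered-ring centroid (π–cation,
recorded against the ring's first atom). Each qualifying pair is reported
once per kind, deterministically ordered.

*Insertion depth.* z_upper − (minimum peptide heavy-atom z), clamped at 0,
using the pocket's upper boundary as the proxy for the membrane's
extracellular surface; the choice of proxy is a convention and is stated
with the number wherever reported.

## Synthetic bundles

The generator builds n (default 7) ideal α-helices (defaults: 1.5 Å rise,
100° twist/residue, 2.3 Å Cα radius, 30 residues) with axes at equal angles
on a circle (default radius 12 Å), alternating N→C direction as in a TM
bundle. Each residue carries N, CA, C, CB and one γ pseudo-atom placed at a
chosen χ1 by internal-coordinate construction, sufficient for rotamer and
contact tests; elements are carbon except backbone N and designated polar
probes. The toggle residue is a TRP at a configurable index of helix 6
(default index 22, placing it in the lower third of the slab), and the
emitted numbering map anchors position 50 two residues past it. Helix
phases are drawn from the seeded generator, so bundles are bit-reproducible
per seed and differ across seeds. Ground truth (axis polygon, z bounds,
analytic prism volume = shoelace area × height for untilted bundles,
applied perturbations) is computed from the construction parameters, not
from the pipeline under test.

What the bundles do **not** emulate: loops, sequence, realistic sidechain
packing, irregular helices, or atoms of a bound ligand/G protein. Passing
synthetic tests therefore demonstrates the correctness of the geometry and
its accounting, not the biological accuracy of any particular boundary
convention on real receptors; the published-value reproduction path (user-
supplied deposited models, see README) exercises the latter.

Perturbations apply exact rigid per-helix displacements, rotations about an
axis perpendicular to the helix through its Cα centroid, and χ1
reassignments (γ atom re-placed at the new torsion with bond length and
angle preserved), all recorded in the ground truth for recovery tests.

## Numerical choices and degenerate inputs

Edge-on-polygon points count inside (tolerance 1e-9); nearest-z-level ties
resolve to the lower level; nearest-Cα fallback ties resolve to the lower
residue number; rotation matrices are validated orthonormal with det +1 to
1e-6; zero-length axes, <3 superposition points, <5 axis points, empty
atom groups and sub-1000-sample Monte-Carlo requests are rejected with
categorized errors (input / annotation / geometry / pairing) rather than
propagating NaNs.

## Problem sizes

The test suite and the acceptance script run on bundles of ~1 000 atoms
with grids of up to ~8·10⁵ retained points (0.25 Å spacing) and Monte-Carlo
samples of 1.2–2·10⁵ per bundle — sizes chosen so the statistical bounds
asserted (3 SE + discretization) are tight enough to catch real defects
while the whole suite completes in well under a minute.
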