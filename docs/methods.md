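# Methods

This note records the models, conventions and numerical choices behind
the package, and what its synthetic benchmarks do and do not establish.

## Structure model

Input is a PDB file with at least two protein chains; the first two
protein chains in file order become monomers a and b of the dimer.  Only
model 1 of multi-model files is used (crystal structures; NMR ensembles
are out of scope, as are mmCIF files and symmetry-built assemblies).
Cleaning removes waters, ligands, cofactors and hydrogens; alternate
locations are resolved to the highest-occupancy copy with alphabetical
tie-break; duplicate residue/atom records collapse to the first; common
modified residues (MSE, SEP, PTR, ...) are renamed to their standard
parents, anything else nonstandard is dropped with a warning.  Author
residue numbering (with insertion codes) is preserved throughout — keys
are (chain, seq_id, icode) — and never renumbered.

Every atom carries a Bondi van der Waals radius (per element) and a
reference volume.  The reference-volume table is a condensed set of
class averages (backbone N/CA/C/O; methyl, methylene, branched-CH,
aromatic and carboxyl/amide-sp² carbons; side-chain N/O/S) rounded from
published Voronoi-volume surveys of protein structures, with the classic
flat 20.1 Å³ as fallback for anything unclassified.  Both tables are
plain dicts and can be swapped by the caller; no descriptor in this
package is sensitive to the volume table beyond an overall scale of C_x.

Membrane proteins oriented in the OPM convention carry two planes of DUM
pseudo-atoms; the slab [min z, max z] over DUM atoms splits residues
into `lipid` (Cα inside the slab) and `aqueous` environments, which the
aggregation step keeps separate.  Without a slab all residues are
aqueous.

## Solvent accessibility and regions

SASA uses the Shrake–Rupley construction: each atom inflated by the
probe radius (1.4 Å water default) is sampled with n points (default
960) and a point counts as exposed when outside every neighboring
inflated sphere.  Sample points come from a deterministic golden-section
spiral, so results are bit-reproducible and independent of any seed; a
seeded Monte-Carlo point set is available behind `method="random"`.
Doubling the point count moves per-residue values by well under 1% on
the benchmark fixtures.

Relative accessibility rASA divides residue SASA by the residue type's
maximum in an extended Gly–X–Gly tripeptide (bundled Tien et al. 2013
theoretical maxima; the convention, not the specific table, is what
matters, and the table is replaceable).  rASA may exceed 1 at termini;
values are never clamped in output.

Monomer-state SASA is computed on each extracted monomer alone — the
complex is disassembled, not masked.  Classification follows the
core/rim/support decomposition of interfaces: with cutoff 0.25 and a
tolerance on ΔrASA = rASA_monomer − rASA_complex,

* ΔrASA ≤ tol: `interior` if rASA_complex < 0.25 else `surface`;
* ΔrASA > tol: `support` if rASA_monomer < 0.25, `rim` if
  rASA_complex ≥ 0.25, else `core`.

The tolerance (default 1e-3 rASA units) separates genuine burial from
point-sampling noise; the protocol it implements states no tolerance, so
this is a package choice, fixed once.  The compact-interface filter
counts buried interface residues (core + support over both monomers)
against a per-category minimum: 14 (cytoplasmic α), 17 (cytoplasmic β),
18 (membrane).  Buried surface area is SASA(a) + SASA(b) − SASA(ab),
clipped to 0 within −1 Å² of sampling noise; its hydrophobic free-energy
equivalent uses 25 cal mol⁻¹ Å⁻².

## Patches and solvent vectors

For each surface residue (rASA_monomer ≥ 0.25 in its own monomer —
interface residues count as surface in the monomeric state), the local
center of mass C_m pools the residue with its 10 nearest surface
residues (Cα–Cα distance, ties broken by residue key); the solvent
vector V_s is the unit vector opposite V_i = C_m − Cα.  Residues whose
|V_i| falls below 1e-6 Å have no defined outward direction and are
excluded as patch centers.  A patch of size n scans candidates in order
of increasing Cα distance and accepts those whose solvent-vector angle
to the center's is strictly below 110°, skipping (not stopping at)
rejected candidates, until n neighbors are accepted; short patches are
returned flagged rather than discarded.  Patch sizes 3, 9, 15, 17 and 20
are the analysis defaults (residue counts; a stray "Å" phrasing for
patch size in the source protocol is read as a typo).  Candidates are
restricted to the same monomer.

## Shape descriptors

**Protrusion index.**  For each heavy atom, V_int sums the reference
volumes of all atoms whose centers lie within a 10 Å sphere (no partial-
volume clipping — the cited definition's convention); C_x = (V_sphere −
V_int)/V_int, and a residue's C_x is the mean over its atoms.  If
packing pushes V_int past the sphere volume the atom is flagged
saturated with C_x = 0.

**Roughness.**  Total SASA of the atom set is scanned over probe radii
0.2–4.0 Å in 0.1 Å steps (the full grid, including sub-water probes) and
the derivative d log SASA / d log R is estimated as the mean of adjacent
finite-difference slopes in log–log space.  This estimator equals the
grid-averaged local derivative to a fraction of a percent (for a single
sphere the closed form is 2R/(r+R)); a single global least-squares line
is available via `estimator="least_squares"` but systematically
underweights the high-R end of a linear grid and is not the default.
The reported roughness is −slope, so rougher surfaces (which lose
crevice area faster as the probe grows) score higher; smooth convex
bodies score negative.  Patch roughness is evaluated on the patch atoms
in isolation (occlusion by non-patch atoms off by default), and the
probe-scan point count is configurable separately from the region-
classification SASA because the scan multiplies cost by the grid size.

**Planarity.**  The rmsd of patch atoms from their total-least-squares
plane (principal-axis solution through the centroid, the exact minimizer
of summed squared orthogonal distances).  Collinear or <3-atom inputs
are rejected.  Per-residue variants of roughness/planarity use the
single residue's atoms.

All three descriptors are rigid-motion invariant; for roughness the
invariance holds to SASA sampling precision since the spiral point set
does not co-rotate with the body.

## Composition, propensity, contacts

%mrc is the per-structure percentage of each amino-acid type in a
region, averaged over structures (structures with an empty region do not
contribute to that region's mean).  Propensity
P(i_k/m) = [ΣSASA of type i in k / ΣSASA in k] ÷ [the same in m] uses
monomer-state SASA; it is 1 when the two regions have identical
SASA-weighted compositions, 0 when type i is absent from k, and missing
(never infinite) when absent from m.  A residue-count-weighted variant
is available.  The four reported comparisons are interface/surface,
rim/surface, core/surface, support/interior.

Contacts are evaluated per cross-monomer residue pair from minimum
heavy-atom distances of the backbone {N, CA, C, O(, OXT)} and side-chain
atom groups: thresholds 6 Å (bb–bb), 5 Å (bb–sc, either direction), 4 Å
(sc–sc); any passing class makes the pair a contact, each pair counts
once, and the primary class is the smallest-threshold class passed.
Observed frequency C_ij counts unordered type pairs over the total
contact count (diagonal once; the unordered-pair sum is 1).  The
expected frequency under random pairing from the interface composition f
(core+rim+support residues pooled over both monomers) is
C_exp,ij = (2−δ_ij) f_i f_j, and the score is S_ij = log₂(C_ij/C_exp,ij)
so that S = 0 means random association; the plain ratio is available
behind a flag, and cells with no observed contacts are reported missing.

## Bayesian two-group comparison

Descriptor distributions of two regions are compared with a robust
hierarchical model in the BEST tradition: per-group mean and scale,
Student-t likelihood with a shared normality parameter ν (a
normal-likelihood mode exists).  Priors are weakly informative on the
data scale — means ~ Normal(pooled mean, 10 × pooled SD), scales ~
half-normal(10 × pooled SD), ν − 1 ~ Exponential(mean 29).  The
posterior of b = (μ₁−μ₂)/√((σ₁²+σ₂²)/2) (root-mean-square pooling;
sample-size-weighted pooling behind a flag) is summarized by its mean
and the 97% highest-density interval, computed as the shortest
contiguous window over the sorted draws.

Sampling uses an affine-invariant ensemble (emcee): 32 walkers, 1000
warmup and 2000 kept steps per walker by default, fully deterministic
given the seed.  Ensemble samplers have no divergence diagnostic, so
convergence is flagged from the mean acceptance fraction and the
integrated-autocorrelation effective sample size of the b chain;
non-convergence flags the result rather than raising.  Groups larger
than 20,000 values are subsampled (seeded) before sampling.  Region
pooling across structures defaults to pooled residues, with a
per-structure-means mode.  Calibration on simulated normal data (97%
HDI coverage over replicates at true b of 0, 0.5 and 2) sits at the
nominal level in the test suite.

## Synthetic fixtures

The generators provide geometry with an answer key, emulating the three
study categories at desk scale:

* **Planar slab**: two n_x × n_y residue grids (4-atom backbone, side
  chains pointing into the gap; non-Gly residues carry CB at 1.53 Å and
  a CG tip at 3.0 Å) facing each other.  Defaults — 6×6 residues,
  4.8 Å lateral spacing, 4.0 Å tip-plane separation — give a tightly
  packed interface: all side-chain-bearing facing residues are within
  the 5 Å ground-truth distance and the buried-residue count clears the
  compact-interface minimums.  Separation is validated against the
  carbon van der Waals diameter.
* **Helix pair**: canonical α-helices (1.5 Å rise, 100°/residue, Cα
  radius 2.3 Å), the partner phase-rotated to face the first, optionally
  antiparallel, at a stated axis separation.
* **Sheet pair**: flat β-sheets (3.3 Å rise, 4.8 Å strand spacing) with
  side chains alternating across the sheet plane, stacked face to face.
* **Noisy sphere**: golden-spiral carbon shell with seeded Gaussian
  radial noise; amplitude 0 is exactly smooth.  For solvent-vector
  oracles the useful regime is curvature on the patch scale (e.g. 100
  atoms on a 10 Å sphere): on much finer spheres the lateral anisotropy
  of any 10-neighbor patch rivals the curvature sag and outward vectors
  are genuinely ill-determined.
* **Two-group samples**: normal draws with an exact true standardized
  difference under the rms pooling convention.

Ground-truth interface sets are recomputed from the emitted coordinates
by an independent 5 Å all-pairs scan, so they stay consistent under any
generator change.  Residue types cycle through a configurable
composition (default: all 20 types), giving the composition, propensity
and contact statistics realistic 20-type input.

What the fixtures do not emulate: real rotamers and packing densities,
missing residues and crystallographic artifacts, membrane lipids as
atoms, and the size distribution of real dimers.  Passing tests
demonstrate correctness of the geometry, statistics and plumbing, not
biological effect sizes; the per-category numbers of the source protocol
require its full structure set, which is outside this package's scope.

## Problem sizes and runtime choices

The bundled tests and the acceptance script run on 72–128-residue
dimers, 100–400-atom spheres and group sizes of 40–1000, with SASA point
counts of 240–960, patch sizes (3, 9) and a coarsened (0.4 Å step)
roughness grid; these sizes were chosen so the whole suite completes on
one CPU in a few minutes while every stage and oracle stays active.  The
pipeline defaults (960 points, all five patch sizes, full 0.1 Å grid)
reproduce the protocol faithfully and cost correspondingly more per
structure.
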