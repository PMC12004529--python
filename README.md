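# dimerface

Structural characterization of protein–protein interfaces in homodimers:
where the interface is, what it is made of, and which geometric
descriptors separate it from the rest of the protein surface.

Given a two-chain homodimer (PDB format, heavy atoms), the package

1. cleans the structure (waters, ligands, cofactors, hydrogens removed;
   altlocs resolved; nonstandard residues mapped to their parents),
2. computes per-atom/per-residue solvent-accessible surface area (SASA)
   by the Shrake–Rupley method, in the complex and in each monomer alone,
3. assigns every residue to one of five locations from its relative
   accessibility rASA = SASA / maxSASA(Gly–X–Gly) at the 0.25 cutoff:

   | ΔrASA ≤ tol | ΔrASA > tol (interface) |
   |---|---|
   | **interior** (buried) / **surface** (exposed) | **support** (buried in the monomer) / **core** (buried on binding) / **rim** (still exposed) |

4. computes four structural descriptors — SASA, protrusion index
   C_x = V_ext/V_int in a 10 Å sphere, surface roughness
   −∂ log SASA/∂ log R over a 0.2–4.0 Å probe scan, and surface planarity
   (rmsd of a surface patch from its least-squares plane) — on solvent-
   vector-consistent patches of 3/9/15/17/20 surface neighbors,
5. collects inter-monomer residue contacts (6/5/4 Å backbone–backbone /
   backbone–side-chain / side-chain–side-chain thresholds), observed
   contact frequencies C_ij and log₂ observed/expected scores S_ij,
   residue compositions (%mrc) and SASA-weighted location propensities,
6. compares descriptor distributions between regions with a robust
   Bayesian two-group model (Student-t likelihood, MCMC), reporting the
   standardized effect size b = (μ₁−μ₂)/√((σ₁²+σ₂²)/2) with a 97%
   highest-density interval.

It is aimed at structural bioinformaticians studying protein–protein
recognition, and is testable end to end without any downloads: the
`synth` module generates dimers (planar slabs, ideal α-helix and β-sheet
pairs) and noisy spheres with geometrically known ground truth.

## Worked example

```python
from collections import Counter
import dimerface as df

dimer, truth = df.make_planar_slab_dimer(seed=1)   # known interface
sasa_a  = df.shrake_rupley(dimer.monomer_a)
sasa_b  = df.shrake_rupley(dimer.monomer_b)
sasa_ab = df.shrake_rupley(dimer.all_residues())

rasa_m = {**df.relative_asa(sasa_a, dimer.monomer_a),
          **df.relative_asa(sasa_b, dimer.monomer_b)}
rasa_c = df.relative_asa(sasa_ab, dimer.all_residues())
assignment = df.classify_regions(rasa_m, rasa_c)
bsa = df.buried_surface_area(sasa_a.total, sasa_b.total, sasa_ab.total)

print(Counter(assignment.region.values()))
print(round(bsa), "A^2 buried ->",
      df.hydrophobic_free_energy(bsa), "kcal/mol")
```

prints

```
Counter({'rim': 46, 'core': 22, 'surface': 4})
1454 A^2 buried -> 36.4 kcal/mol
```

i.e. all 68 constructed interface residues land in interface regions
(46 rim + 22 core), and burying 1454 Å² corresponds to ≈36 kcal/mol of
hydrophobic free energy at the 25 cal mol⁻¹ Å⁻² conversion.  The
Bayesian comparison recovers known effects:

```python
sample = df.sample_two_group(n1=400, n2=400, true_b=0.8, seed=3)
result = df.effect_size(sample)   # -> b = 0.816, 97% HDI [0.652, 0.989]
```

The `examples/` directory has one short script per capability; the
`dimerface` CLI (`run`, `batch`, `aggregate`, `synth`) wraps the same
functions for shell use, writing per-residue TSV tables and category
reports (effect sizes, %mrc, propensities, contact matrices) as CSV.

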