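"""Protrusion, roughness and planarity on controlled geometry.

A smooth sphere against the same sphere with radial noise shows how the
roughness scan reacts; a sphere cap illustrates planarity; an isolated
atom gives the textbook protrusion value.
"""

import numpy as np

import dimerface as df
from dimerface.data import FLAT_ATOM_VOLUME
from dimerface.descriptors import planarity, protrusion_index, roughness
from dimerface.model import flatten

# protrusion index: an isolated atom has almost the whole 10 A sphere free
iso = [df.Residue("X", 1, "ALA", [df.Atom("C1", "C", (0, 0, 0),
                                          ref_volume=FLAT_ATOM_VOLUME)])]
cx = protrusion_index(iso, radius=10.0).per_atom_cx[0]
print(f"isolated-atom Cx = {cx:.1f}  (free/occupied volume in a 10 A sphere)")

# roughness: minus the slope of log SASA vs log probe radius
for amp in (0.0, 0.75, 1.5):
    atoms = df.make_noisy_sphere(300, radius=12.0, noise_amplitude=amp,
                                 seed=5)
    arr = flatten(df.sphere_as_residues(atoms))
    r = roughness(arr.coords, arr.radii, n_points=100)
    print(f"radial noise {amp:>4.2f} A -> roughness {r.roughness:+.3f}")
# Rougher shells lose crevice area faster as the probe grows, so the
# roughness value increases with the noise amplitude.

# planarity: rmsd from the total-least-squares plane
atoms = df.make_noisy_sphere(400, radius=12.0, noise_amplitude=0.0, seed=0)
cap = np.array([a.coords for a in atoms if a.coords[2] > 10.0])
print(f"sphere-cap planarity rmsd = {planarity(cap).rmsd:.2f} A "
      f"({len(cap)} atoms; flatter patches give smaller rmsd)")
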