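"""Synthetic dimers and samples with known ground truth.

Generators for geometry with a controllable answer key:

* planar-slab dimers - two flat residue grids facing each other, with
  side-chain pseudo-atoms pointing across the gap so all three contact
  classes occur;
* ideal alpha-helix and beta-sheet dimers - canonical backbone geometry
  packed at a stated separation, emulating helical and strand interfaces;
* noisy spheres - atom shells with controllable radial roughness, the
  control fixture for the roughness and planarity descriptors;
* two-group samples with a stated true standardized effect size.

Residue geometry is deliberately coarse (4 backbone atoms plus up to two
side-chain pseudo-atoms): the descriptors need coordinates, radii and
volumes, not rotamer realism.  Every generator is deterministic under a
fixed seed, and each dimer carries a ground truth recomputable from the
emitted coordinates by an independent distance scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import data
from .bayes import TwoGroupSample
from .model import Atom, Dimer, Residue

#: Cross-monomer heavy-atom distance (A) defining the constructed
#: interface truth set.
TRUTH_CONTACT_DISTANCE = 5.0

#: Residues given a second side-chain pseudo-atom (larger side chains).
_LARGE = frozenset({"ARG", "GLN", "GLU", "HIS", "ILE", "LEU", "LYS",
                    "MET", "PHE", "TRP", "TYR"})


@dataclass(slots=True)
class GroundTruth:
    interface_a: set = field(default_factory=set)   # ResidueKeys, monomer a
    interface_b: set = field(default_factory=set)
    composition: dict = field(default_factory=dict)  # res_type -> count

    @property
    def interface(self) -> set:
        return self.interface_a | self.interface_b


def _cycle_types(n: int, composition: list[str] | None) -> list[str]:
    pool = composition or list(data.AMINO_ACIDS)
    return list(itertools.islice(itertools.cycle(pool), n))


def _atom(name: str, element: str, xyz: np.ndarray, res_type: str) -> Atom:
    return Atom(
        name=name, element=element, coords=tuple(float(v) for v in xyz),
        vdw_radius=data.vdw_radius(element),
        ref_volume=data.reference_volume(res_type, name, element),
    )


def _make_residue(chain: str, seq: int, res_type: str, origin: np.ndarray,
                  inward: np.ndarray, along: np.ndarray,
                  rng: np.random.Generator | None, noise: float) -> Residue:
    """Coarse residue: N-CA-C-O in the slab plane, side chain along ``inward``."""
    across = np.cross(inward, along)
    across /= np.linalg.norm(across)
    atoms = [
        ("N", "N", origin - 1.25 * along),
        ("CA", "C", origin),
        ("C", "C", origin + 1.25 * along),
        ("O", "O", origin + 1.25 * along + 1.24 * across),
    ]
    if res_type != "GLY":
        atoms.append(("CB", "C", origin + 1.53 * inward))
        atoms.append(("CG", "C", origin + 3.0 * inward))
    built = []
    for name, el, xyz in atoms:
        if rng is not None and noise > 0:
            xyz = xyz + rng.normal(0.0, noise, 3)
        built.append(_atom(name, el, xyz, res_type))
    return Residue(chain, seq, res_type, built)


def recompute_truth(dimer: Dimer,
                    cutoff: float = TRUTH_CONTACT_DISTANCE) -> GroundTruth:
    """Independent all-pairs distance scan over the emitted coordinates."""
    ca = np.concatenate([r.coord_array() for r in dimer.monomer_a])
    cb = np.concatenate([r.coord_array() for r in dimer.monomer_b])
    owners_a = np.concatenate([
        np.full(len(r.atoms), i) for i, r in enumerate(dimer.monomer_a)])
    owners_b = np.concatenate([
        np.full(len(r.atoms), i) for i, r in enumerate(dimer.monomer_b)])
    d = cdist(ca, cb)
    close = d <= cutoff
    ia = {dimer.monomer_a[i].key for i in np.unique(owners_a[close.any(axis=1)])}
    ib = {dimer.monomer_b[j].key for j in np.unique(owners_b[close.any(axis=0)])}
    comp: dict[str, int] = {}
    for r in dimer.all_residues():
        comp[r.res_type] = comp.get(r.res_type, 0) + 1
    return GroundTruth(ia, ib, comp)


# ---------------------------------------------------------------------------
# planar slab
# ---------------------------------------------------------------------------

def make_planar_slab_dimer(n_x: int = 6, n_y: int = 6, spacing: float = 4.8,
                           separation: float = 4.0, noise: float = 0.0,
                           seed: int = 0,
                           composition: list[str] | None = None,
                           ) -> tuple[Dimer, GroundTruth]:
    """Two flat residue grids facing each other across a gap.

    ``separation`` is the gap between the opposing side-chain tip planes;
    side chains of both monomers point into the gap, so facing residues
    make bb-bb, bb-sc and sc-sc contacts at small separations.  Interface
    ground truth is recomputed from the coordinates with a 5 A scan.
    """
    if n_x < 4 or n_y < 4:
        raise ValueError("slab grid must be at least 4x4 residues per monomer")
    if separation <= 3.4:  # carbon van der Waals diameter
        raise ValueError("separation must exceed the atomic diameter (3.4 A)")
    rng = np.random.default_rng(seed)
    types = _cycle_types(n_x * n_y, composition)
    # tip planes: A side-chain tips at z = 0, B tips at z = separation
    tip = 3.0
    z_a, z_b = -tip, separation + tip
    monos = []
    for chain, z0, inward in (("A", z_a, np.array([0.0, 0.0, 1.0])),
                              ("B", z_b, np.array([0.0, 0.0, -1.0]))):
        residues = []
        seq = 0
        for iy in range(n_y):
            for ix in range(n_x):
                seq += 1
                origin = np.array([ix * spacing, iy * spacing, z0])
                residues.append(_make_residue(
                    chain, seq, types[seq - 1], origin, inward,
                    np.array([1.0, 0.0, 0.0]),
                    rng if noise > 0 else None, noise))
        monos.append(residues)
    dimer = Dimer(monos[0], monos[1],
                  id=f"slab_{n_x}x{n_y}_sep{separation:g}_seed{seed}")
    return dimer, recompute_truth(dimer)


# ---------------------------------------------------------------------------
# noisy sphere
# ---------------------------------------------------------------------------

def make_noisy_sphere(n_atoms: int = 400, radius: float = 12.0,
                      noise_amplitude: float = 0.0, seed: int = 0,
                      ) -> list[Atom]:
    """Carbon-atom shell with Gaussian radial noise (roughness fixture).

    Directions come from the deterministic golden spiral; only the radial
    displacement is random, so amplitude 0 gives a perfectly smooth shell
    regardless of seed.
    """
    if n_atoms < 50:
        raise ValueError("sphere fixture needs at least 50 atoms")
    rng = np.random.default_rng(seed)
    k = np.arange(n_atoms, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_atoms
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    radii = np.full(n_atoms, float(radius))
    if noise_amplitude > 0:
        radii += noise_amplitude * rng.standard_normal(n_atoms)
    return [_atom("C1", "C", dirs[i] * radii[i], "ALA")
            for i in range(n_atoms)]


def sphere_as_residues(atoms: list[Atom], chain: str = "S") -> list[Residue]:
    """Wrap sphere atoms one-per-residue so residue-level ops apply."""
    return [Residue(chain, i + 1, "ALA", [a]) for i, a in enumerate(atoms)]


# ---------------------------------------------------------------------------
# helix / sheet pairs
# ---------------------------------------------------------------------------

def _ideal_helix(chain: str, n_res: int, types: list[str],
                 phase: float = 0.0) -> list[Residue]:
    """Canonical alpha helix along z: 1.5 A rise, 100 deg twist, r = 2.3 A."""
    residues = []
    r_ca = 2.3
    for k in range(n_res):
        ang = np.radians(100.0 * k) + phase
        ca = np.array([r_ca * np.cos(ang), r_ca * np.sin(ang), 1.5 * k])
        ang_p = np.radians(100.0 * (k - 1)) + phase
        ang_n = np.radians(100.0 * (k + 1)) + phase
        prev = np.array([r_ca * np.cos(ang_p), r_ca * np.sin(ang_p), 1.5 * (k - 1)])
        nxt = np.array([r_ca * np.cos(ang_n), r_ca * np.sin(ang_n), 1.5 * (k + 1)])
        to_prev = (prev - ca) / np.linalg.norm(prev - ca)
        to_next = (nxt - ca) / np.linalg.norm(nxt - ca)
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        rt = types[k]
        atoms = [
            _atom("N", "N", ca + 1.46 * to_prev, rt),
            _atom("CA", "C", ca, rt),
            _atom("C", "C", ca + 1.52 * to_next, rt),
            _atom("O", "O", ca + 1.52 * to_next + 1.23 * radial, rt),
        ]
        if rt != "GLY":
            atoms.append(_atom("CB", "C", ca + 1.53 * radial, rt))
            if rt in _LARGE:
                atoms.append(_atom("CG", "C", ca + 3.0 * radial, rt))
        residues.append(Residue(chain, k + 1, rt, atoms))
    return residues


def make_helix_pair(n_res: int = 20, separation: float = 10.0,
                    antiparallel: bool = True, seed: int = 0,
                    composition: list[str] | None = None,
                    ) -> tuple[Dimer, GroundTruth]:
    """Two ideal alpha helices packed side by side (helical interface).

    ``separation`` is the axis-to-axis distance.  The partner helix is
    phase-rotated so its side chains face the first helix; antiparallel
    bundles flip the partner's z axis.  Noise-free and deterministic: the
    seed only affects nothing here and is accepted for interface symmetry.
    """
    if n_res < 10:
        raise ValueError("helix needs at least 10 residues per unit")
    if separation <= 4.0:
        raise ValueError("axial separation too small: helices overlap")
    types = _cycle_types(n_res, composition)
    ha = _ideal_helix("A", n_res, types, phase=0.0)
    hb = _ideal_helix("B", n_res, types, phase=np.pi)
    moved = []
    height = 1.5 * (n_res - 1)
    for res in hb:
        atoms = []
        for a in res.atoms:
            x, y, z = a.coords
            if antiparallel:
                y, z = -y, height - z
            atoms.append(Atom(a.name, a.element, (x + separation, y, z),
                              a.occupancy, a.altloc, a.vdw_radius, a.ref_volume))
        moved.append(Residue(res.chain_id, res.seq_id, res.res_type, atoms))
    dimer = Dimer(ha, moved, id=f"helixpair_{n_res}_sep{separation:g}")
    return dimer, recompute_truth(dimer)


def make_sheet_pair(n_strands: int = 4, n_res: int = 8,
                    strand_spacing: float = 4.8, rise: float = 3.3,
                    separation: float = 9.0,
                    composition: list[str] | None = None,
                    seed: int = 0) -> tuple[Dimer, GroundTruth]:
    """Two flat beta sheets stacked face to face (strand interface).

    Each monomer is ``n_strands`` extended strands in a plane; side chains
    alternate above/below the sheet plane, so half of each sheet's side
    chains point into the packing gap.  ``separation`` is the distance
    between the two sheet planes.
    """
    if n_res < 4 or n_strands < 2:
        raise ValueError("sheet needs >=2 strands of >=4 residues")
    if separation <= 3.4:
        raise ValueError("sheet separation must exceed the atomic diameter")
    n_total = n_strands * n_res
    types = _cycle_types(n_total, composition)
    monos = []
    for chain, z0, flip in (("A", 0.0, 1.0), ("B", separation, -1.0)):
        residues = []
        seq = 0
        for s in range(n_strands):
            for k in range(n_res):
                seq += 1
                rt = types[seq - 1]
                origin = np.array([s * strand_spacing, k * rise, z0])
                # side chains alternate along the strand; flip selects the
                # face pointing into the gap for each monomer
                inward = np.array([0.0, 0.0, flip * (1.0 if k % 2 == 0 else -1.0)])
                residues.append(_make_residue(
                    chain, seq, rt, origin, inward,
                    np.array([0.0, 1.0, 0.0]), None, 0.0))
        monos.append(residues)
    dimer = Dimer(monos[0], monos[1],
                  id=f"sheetpair_{n_strands}x{n_res}_sep{separation:g}")
    return dimer, recompute_truth(dimer)


# ---------------------------------------------------------------------------
# two-group samples
# ---------------------------------------------------------------------------

def sample_two_group(n1: int, n2: int, true_b: float,
                     sd_ratio: float = 1.0, seed: int = 0) -> TwoGroupSample:
    """Normal two-group sample with a stated true standardized effect size.

    Group 1 ~ N(true_b * s_pool, 1), group 2 ~ N(0, sd_ratio), where
    s_pool = sqrt((1 + sd_ratio^2)/2), so the population effect size under
    the root-mean-square pooling convention is exactly ``true_b``.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    s_pool = np.sqrt((1.0 + sd_ratio ** 2) / 2.0)
    v1 = rng.normal(true_b * s_pool, 1.0, n1)
    v2 = rng.normal(0.0, sd_ratio, n2)
    return TwoGroupSample("group1", "group2", v1, v2)
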