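"""Shrake-Rupley solvent accessibility and the five-region classification.

Every residue of a dimer is assigned to one of five locations by comparing
its relative accessibility (rASA) in the isolated monomer with that in the
complex:

* ``interior`` - buried in the monomer and unchanged on complexation,
* ``surface``  - exposed and unchanged,
* ``core``     - exposed in the monomer, buried in the complex,
* ``rim``      - at the interface but still exposed in the complex,
* ``support``  - at the interface but already buried in the monomer.

The interface is the set {core, rim, support}: residues whose rASA drops
when the partner binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import data
from .model import AtomArrays, Residue, ResidueKey, flatten

DEFAULT_PROBE = 1.4          # water probe radius, A
DEFAULT_N_POINTS = 960
DEFAULT_RASA_CUTOFF = 0.25   # interior/exposed threshold on rASA
DEFAULT_DELTA_TOL = 1e-3     # rASA units; separates burial from sampling noise
REGIONS = ("interior", "surface", "core", "rim", "support")
INTERFACE_REGIONS = ("core", "rim", "support")

#: Minimum buried (core+support) residues for a tightly packed interface,
#: per structural category.
MIN_BURIED_BY_CATEGORY = {
    "cytoplasmic_alpha": 14,
    "cytoplasmic_beta": 17,
    "membrane": 18,
}

HYDROPHOBIC_ENERGY_CAL_PER_A2 = 25.0  # cal/mol per A^2 of buried area


@dataclass(slots=True)
class SasaResult:
    probe_radius: float
    n_points: int
    per_atom: np.ndarray                      # A^2, aligned with the atom flat order
    per_residue: dict[ResidueKey, float]      # A^2

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass(slots=True)
class RegionAssignment:
    rasa_monomer: dict[ResidueKey, float]
    rasa_complex: dict[ResidueKey, float]
    delta_rasa: dict[ResidueKey, float]
    region: dict[ResidueKey, str]

    def residues_in(self, *regions: str) -> list[ResidueKey]:
        want = set(regions)
        return [k for k, r in self.region.items() if r in want]


def sphere_points(n: int, method: str = "golden", seed: int = 0) -> np.ndarray:
    """Unit sphere sample points.

    ``golden`` (default) is the deterministic golden-section spiral, so
    SASA values are bit-reproducible and the seed is ignored;
    ``random`` draws uniform directions from a seeded generator.
    """
    if n < 16:
        raise ValueError("need at least 16 sphere points")
    if method == "golden":
        k = np.arange(n, dtype=float)
        z = 1.0 - (2.0 * k + 1.0) / n
        theta = np.pi * (1.0 + 5.0 ** 0.5) * k
        rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    if method == "random":
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ValueError(f"unknown point method: {method!r}")


def shrake_rupley_atoms(coords: np.ndarray, radii: np.ndarray,
                        probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_N_POINTS,
                        method: str = "golden", seed: int = 0) -> np.ndarray:
    """Per-atom SASA (A^2) for arbitrary spheres.

    Each atom is expanded by the probe radius and sampled with ``n_points``
    test points; a point is exposed when it lies outside every neighbouring
    expanded sphere.  Area = exposed fraction x 4 pi (r + probe)^2.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if len(coords) == 0:
        raise ValueError("need at least one atom")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    pts = sphere_points(n_points, method=method, seed=seed)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = float(expanded.max())
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        r_i = expanded[i]
        surface = coords[i] + pts * r_i
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r_i + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", surface - coords[j], surface - coords[j])
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.sum() / n_points * 4.0 * np.pi * r_i ** 2
    return areas


def shrake_rupley(residues: list[Residue] | AtomArrays,
                  probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS,
                  method: str = "golden", seed: int = 0) -> SasaResult:
    """SASA of a residue set; per-residue values sum their atoms."""
    arrays = residues if isinstance(residues, AtomArrays) else flatten(residues)
    per_atom = shrake_rupley_atoms(arrays.coords, arrays.radii,
                                   probe=probe, n_points=n_points,
                                   method=method, seed=seed)
    per_res: dict[ResidueKey, float] = {}
    for idx, res in enumerate(arrays.residues):
        mask = arrays.owner == idx
        per_res[res.key] = float(per_atom[mask].sum())
    return SasaResult(probe, n_points, per_atom, per_res)


def relative_asa(sasa: SasaResult, residues: list[Residue],
                 max_table: dict[str, float] | None = None,
                 ) -> dict[ResidueKey, float]:
    """rASA = residue SASA / maximum Gly-X-Gly SASA of its type.

    Values may exceed 1 (chain termini, distorted conformations); they are
    only clamped downstream for classification, never here.
    """
    table = max_table if max_table is not None else data.MAX_SASA_GXG
    out: dict[ResidueKey, float] = {}
    for res in residues:
        if res.res_type not in table:
            raise KeyError(
                f"no maximum-SASA entry for residue {res.res_type} at {res.key}")
        out[res.key] = sasa.per_residue[res.key] / table[res.res_type]
    return out


def classify_regions(rasa_monomer: dict[ResidueKey, float],
                     rasa_complex: dict[ResidueKey, float],
                     cutoff: float = DEFAULT_RASA_CUTOFF,
                     tol: float = DEFAULT_DELTA_TOL) -> RegionAssignment:
    """Five-location assignment from monomer vs complex rASA.

    delta rASA <= tol: interior when buried in the complex, surface
    otherwise.  delta rASA > tol (interface): support when already buried
    in the monomer, rim when still exposed in the complex, core when the
    residue goes from exposed to buried.
    """
    if set(rasa_monomer) != set(rasa_complex):
        raise ValueError("monomer and complex rASA cover different residues")
    delta: dict[ResidueKey, float] = {}
    region: dict[ResidueKey, str] = {}
    for key, rm in rasa_monomer.items():
        rc = rasa_complex[key]
        d = rm - rc
        delta[key] = d
        if d <= tol:
            region[key] = "interior" if rc < cutoff else "surface"
        elif rm < cutoff:
            region[key] = "support"
        elif rc >= cutoff:
            region[key] = "rim"
        else:
            region[key] = "core"
    return RegionAssignment(dict(rasa_monomer), dict(rasa_complex), delta, region)


def buried_surface_area(sasa_a: float, sasa_b: float, sasa_ab: float) -> float:
    """BSA = SASA(A) + SASA(B) - SASA(AB), clipped at 0 for sampling noise."""
    if min(sasa_a, sasa_b, sasa_ab) < 0:
        raise ValueError("SASA inputs must be non-negative")
    bsa = sasa_a + sasa_b - sasa_ab
    if bsa < -1.0:
        raise ValueError(
            f"BSA = {bsa:.2f} A^2 < -1: inconsistent SASA inputs")
    return max(bsa, 0.0)


def hydrophobic_free_energy(bsa: float) -> float:
    """Hydrophobic transfer free energy in kcal/mol for a buried area.

    Uses the empirical 25 cal/mol per A^2 correspondence between buried
    surface area and hydrophobic free energy.
    """
    if bsa < 0:
        raise ValueError("buried area must be >= 0")
    return bsa * HYDROPHOBIC_ENERGY_CAL_PER_A2 / 1000.0


def interface_size_filter(assignment: RegionAssignment,
                          min_buried: int) -> tuple[bool, int]:
    """Compact-interface filter: count of buried interface residues.

    Buried = {core, support} pooled over both monomers; a structure passes
    when the count reaches the category minimum (14 cytoplasmic alpha /
    17 cytoplasmic beta / 18 membrane).
    """
    n_buried = len(assignment.residues_in("core", "support"))
    return n_buried >= min_buried, n_buried
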