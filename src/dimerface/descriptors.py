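"""Shape descriptors: protrusion index, surface roughness, surface planarity.

* Protrusion index Cx of an atom: free-to-occupied volume ratio inside a
  10 A sphere centred on the atom; a residue's Cx is the mean over its
  atoms.  High Cx = the atom sticks out of the surface.
* Roughness: (minus) the least-squares slope of log SASA against log probe
  radius over a probe grid; rough terrain loses crevice area faster as the
  probe grows, so larger values mean rougher surfaces.
* Planarity: rmsd of a patch's atoms from their total-least-squares plane;
  lower rmsd = flatter patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomArrays, Residue, ResidueKey, flatten
from .sasa import shrake_rupley_atoms

CX_SPHERE_RADIUS = 10.0   # A
ROUGHNESS_PROBE_GRID = tuple(np.round(np.arange(0.2, 4.0 + 1e-9, 0.1), 10))
MIN_ROUGHNESS_POINTS = 5


@dataclass(slots=True)
class ProtrusionResult:
    sphere_radius: float
    per_atom_cx: np.ndarray          # aligned with the context atom order
    per_atom_v_int: np.ndarray       # A^3
    saturated: np.ndarray            # bool; V_int exceeded sphere volume
    per_residue_cx: dict[ResidueKey, float]


@dataclass(slots=True)
class RoughnessResult:
    probe_grid: np.ndarray
    sasa_values: np.ndarray          # total SASA at each retained probe
    slope: float                     # d log SASA / d log R (least squares)
    roughness: float                 # -slope; higher = rougher


@dataclass(slots=True)
class PlanarityResult:
    rmsd: float
    normal: np.ndarray               # unit plane normal
    offset: float                    # plane: normal . x = offset


# ---------------------------------------------------------------------------
# protrusion index
# ---------------------------------------------------------------------------

def protrusion_index(context: list[Residue] | AtomArrays,
                     target_mask: np.ndarray | None = None,
                     radius: float = CX_SPHERE_RADIUS) -> ProtrusionResult:
    """Cx for every target atom within the full heavy-atom context.

    V_int sums the reference volumes of all atoms (the target included)
    whose *centres* lie within ``radius`` of the target; no partial-volume
    clipping.  Cx = (V_sphere - V_int) / V_int.  When packing pushes V_int
    beyond the sphere volume the atom is flagged saturated and Cx set to 0.
    """
    if radius <= 0:
        raise ValueError("sphere radius must be > 0")
    arrays = context if isinstance(context, AtomArrays) else flatten(context)
    n = len(arrays)
    if target_mask is None:
        target_mask = np.ones(n, dtype=bool)
    v_sphere = 4.0 / 3.0 * np.pi * radius ** 3
    tree = cKDTree(arrays.coords)
    v_int = np.zeros(n)
    cx = np.full(n, np.nan)
    saturated = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(target_mask):
        idx = tree.query_ball_point(arrays.coords[i], radius)
        v = float(arrays.volumes[idx].sum())
        v_int[i] = v
        if v > v_sphere:
            saturated[i] = True
            cx[i] = 0.0
        else:
            cx[i] = (v_sphere - v) / v
    per_res: dict[ResidueKey, float] = {}
    for ridx, res in enumerate(arrays.residues):
        vals = cx[(arrays.owner == ridx) & target_mask]
        if vals.size:
            per_res[res.key] = float(vals.mean())
    return ProtrusionResult(radius, cx, v_int, saturated, per_res)


# ---------------------------------------------------------------------------
# roughness
# ---------------------------------------------------------------------------

def roughness(coords: np.ndarray, radii: np.ndarray,
              probes: tuple[float, ...] | np.ndarray = ROUGHNESS_PROBE_GRID,
              n_points: int = 240, method: str = "golden",
              seed: int = 0, estimator: str = "finite_diff") -> RoughnessResult:
    """Log-log probe-radius scan of total SASA for one atom set.

    The derivative d log SASA / d log R is estimated over the probe grid:
    by default as the mean of adjacent finite-difference slopes in log-log
    space (which converges to the grid-averaged local derivative), with a
    single global least-squares line as an alternative
    (``estimator='least_squares'``).  The reported roughness is minus the
    slope so that rougher surfaces score higher.  Grid points where SASA
    vanishes are dropped; fewer than ``MIN_ROUGHNESS_POINTS`` surviving
    points is an error.
    """
    probes = np.asarray(probes, dtype=float)
    if probes.size and not np.all(np.diff(probes) > 0):
        raise ValueError("probe grid must be strictly increasing")
    if np.any(probes <= 0):
        raise ValueError("probe radii must be > 0")
    areas = np.array([
        shrake_rupley_atoms(coords, radii, probe=float(p),
                            n_points=n_points, method=method, seed=seed).sum()
        for p in probes
    ])
    keep = areas > 0
    if keep.sum() < MIN_ROUGHNESS_POINTS:
        raise ValueError(
            f"only {int(keep.sum())} probe points with nonzero SASA "
            f"(need {MIN_ROUGHNESS_POINTS})")
    x = np.log(probes[keep])
    y = np.log(areas[keep])
    if estimator == "finite_diff":
        slope = float(np.mean(np.diff(y) / np.diff(x)))
    elif estimator == "least_squares":
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        raise ValueError(f"unknown slope estimator: {estimator!r}")
    return RoughnessResult(probes[keep], areas[keep], slope, -slope)


def roughness_of(residues: list[Residue], **kw) -> RoughnessResult:
    arrays = flatten(residues)
    return roughness(arrays.coords, arrays.radii, **kw)


# ---------------------------------------------------------------------------
# planarity
# ---------------------------------------------------------------------------

def planarity(coords: np.ndarray) -> PlanarityResult:
    """rmsd of points from their total-least-squares plane.

    The plane through the centroid whose normal is the smallest principal
    axis minimises the sum of squared orthogonal distances; collinear or
    <3-point inputs are degenerate and rejected.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("planarity needs at least 3 atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: only one significant singular value
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("planarity undefined for collinear atoms")
    normal = vt[2]
    rmsd = float(s[2] / np.sqrt(len(pts)))
    return PlanarityResult(rmsd, normal, float(normal @ centroid))


def planarity_of(residues: list[Residue]) -> PlanarityResult:
    return planarity(flatten(residues).coords)
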