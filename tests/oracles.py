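"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: SASA by dense
random sampling with an all-pairs occlusion scan, protrusion by an O(N^2)
distance loop, planarity by a dense grid search over plane normals, and
contacts by an exhaustive per-class distance evaluation.
"""

import numpy as np
from scipy.spatial.distance import cdist


def sasa_dense_sampling(coords, radii, probe=1.4, n_points=9600, seed=0):
    """Per-atom SASA by dense seeded random sampling, all-pairs occlusion."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    expanded = np.asarray(radii, float) + probe
    rng = np.random.default_rng(seed)
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        v = rng.standard_normal((n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + v * expanded[i]
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) > expanded[j]
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def protrusion_bruteforce(coords, volumes, radius=10.0):
    """Cx per atom via an exhaustive pairwise distance scan."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    volumes = np.asarray(volumes, float)
    v_sphere = 4.0 / 3.0 * np.pi * radius ** 3
    out = np.empty(len(coords))
    for i in range(len(coords)):
        d = np.linalg.norm(coords - coords[i], axis=1)
        v_int = volumes[d <= radius].sum()
        out[i] = 0.0 if v_int > v_sphere else (v_sphere - v_int) / v_int
    return out


def planarity_grid_search(coords, n_normals=80000):
    """Minimum rmsd over a dense grid of candidate plane normals."""
    pts = np.asarray(coords, float).reshape(-1, 3)
    pts = pts - pts.mean(axis=0)
    k = np.arange(n_normals, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_normals
    th = np.pi * (1.0 + 5.0 ** 0.5) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    normals = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
    proj = normals @ pts.T                              # (n_normals, n_pts)
    rms = np.sqrt((proj ** 2).mean(axis=1))
    return float(rms.min())


def contacts_bruteforce(monomer_a, monomer_b,
                        thresholds={"bb-bb": 6.0, "bb-sc": 5.0, "sc-sc": 4.0}):
    """Set of contacting residue-key pairs by exhaustive evaluation."""
    bb_names = {"N", "CA", "C", "O", "OXT"}
    pairs = set()
    for ra in monomer_a:
        a_bb = np.array([a.coords for a in ra.atoms if a.name in bb_names])
        a_sc = np.array([a.coords for a in ra.atoms if a.name not in bb_names])
        for rb in monomer_b:
            b_bb = np.array([a.coords for a in rb.atoms if a.name in bb_names])
            b_sc = np.array([a.coords for a in rb.atoms if a.name not in bb_names])
            hit = False
            if len(a_bb) and len(b_bb) and cdist(a_bb, b_bb).min() <= thresholds["bb-bb"]:
                hit = True
            if not hit and len(a_bb) and len(b_sc) and cdist(a_bb, b_sc).min() <= thresholds["bb-sc"]:
                hit = True
            if not hit and len(a_sc) and len(b_bb) and cdist(a_sc, b_bb).min() <= thresholds["bb-sc"]:
                hit = True
            if not hit and len(a_sc) and len(b_sc) and cdist(a_sc, b_sc).min() <= thresholds["sc-sc"]:
                hit = True
            if hit:
                pairs.add((ra.key, rb.key))
    return pairs
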