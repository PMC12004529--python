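"""Protrusion index, surface roughness, and planarity descriptors."""

import numpy as np
import pytest

import dimerface as df
from dimerface.data import FLAT_ATOM_VOLUME
from dimerface.model import flatten
from dimerface.descriptors import planarity, protrusion_index, roughness

from oracles import planarity_grid_search, protrusion_bruteforce


def _carbon(xyz, volume=FLAT_ATOM_VOLUME, name="C1"):
    return df.Atom(name, "C", tuple(map(float, xyz)), vdw_radius=1.7,
                   ref_volume=volume)


def _as_residues(atoms):
    return [df.Residue("X", i + 1, "ALA", [a]) for i, a in enumerate(atoms)]


# ---------------------------------------------------------------------------
# protrusion index
# ---------------------------------------------------------------------------

def test_cx_isolated_atom_arithmetic():
    res = _as_residues([_carbon((0, 0, 0))])
    out = protrusion_index(res, radius=10.0)
    v_sphere = 4.0 / 3.0 * np.pi * 1000.0
    expected = (v_sphere - FLAT_ATOM_VOLUME) / FLAT_ATOM_VOLUME
    assert out.per_atom_cx[0] == pytest.approx(expected)
    assert expected == pytest.approx(207.4, abs=0.05)


def test_cx_half_filled_sphere_is_one():
    # atoms inside the sphere whose volumes sum to exactly half its volume
    v_sphere = 4.0 / 3.0 * np.pi * 1000.0
    rng = np.random.default_rng(2)
    pts = rng.uniform(-4, 4, (24, 3))
    pts[0] = 0.0
    atoms = [_carbon(p, volume=v_sphere / 2.0 / 24) for p in pts]
    out = protrusion_index(_as_residues(atoms), radius=10.0)
    assert out.per_atom_cx[0] == pytest.approx(1.0)


def test_cx_matches_bruteforce_oracle_on_cloud():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 25, (500, 3))
    vols = rng.uniform(8, 38, 500)
    atoms = [_carbon(p, volume=v) for p, v in zip(pts, vols)]
    out = protrusion_index(_as_residues(atoms), radius=10.0)
    oracle = protrusion_bruteforce(pts, vols, radius=10.0)
    np.testing.assert_allclose(out.per_atom_cx, oracle, rtol=1e-12)


def test_cx_saturation_flagged_as_zero():
    pts = np.zeros((3, 3))
    v_sphere = 4.0 / 3.0 * np.pi * 1000.0
    atoms = [_carbon(p, volume=v_sphere) for p in pts]
    out = protrusion_index(_as_residues(atoms), radius=10.0)
    assert out.saturated.all() and np.all(out.per_atom_cx == 0.0)


def test_residue_cx_is_mean_of_atom_cx():
    rng = np.random.default_rng(1)
    res = [df.Residue("A", i + 1, "ALA",
                      [_carbon(rng.uniform(0, 15, 3)) for _ in range(4)])
           for i in range(5)]
    out = protrusion_index(res, radius=10.0)
    arrays = flatten(res)
    for i, r in enumerate(res):
        mask = arrays.owner == i
        assert out.per_residue_cx[r.key] == pytest.approx(
            out.per_atom_cx[mask].mean())


# ---------------------------------------------------------------------------
# roughness
# ---------------------------------------------------------------------------

def test_single_sphere_slope_matches_closed_form():
    r = 1.7
    out = roughness(np.zeros((1, 3)), np.array([r]), n_points=960)
    grid = np.asarray(out.probe_grid)
    analytic = float(np.mean(2.0 * grid / (r + grid)))
    assert abs((-out.roughness) - analytic) / analytic < 0.05


def test_roughness_orders_noise_amplitudes():
    vals = []
    for amp in (0.0, 0.75, 1.5):
        atoms = df.make_noisy_sphere(300, radius=12.0, noise_amplitude=amp,
                                     seed=5)
        arr = flatten(df.sphere_as_residues(atoms))
        vals.append(roughness(arr.coords, arr.radii, n_points=100).roughness)
    assert vals[0] < vals[1] < vals[2]


def test_roughness_scaling_consistency():
    # doubling lengths and the probe grid leaves the log-log slope unchanged
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 12, (40, 3))
    radii = np.full(40, 1.7)
    probes = tuple(np.round(np.arange(0.4, 4.01, 0.4), 10))
    r1 = roughness(pts, radii, probes=probes, n_points=240)
    r2 = roughness(2 * pts, 2 * radii,
                   probes=tuple(2 * p for p in probes), n_points=240)
    assert r1.slope == pytest.approx(r2.slope, rel=1e-9)


def test_roughness_input_validation():
    with pytest.raises(ValueError):
        roughness(np.zeros((1, 3)), np.array([1.7]), probes=(0.5, 0.4, 0.6))
    with pytest.raises(ValueError):
        roughness(np.zeros((1, 3)), np.array([1.7]), probes=(0.2, 0.3, 0.4))


# ---------------------------------------------------------------------------
# planarity
# ---------------------------------------------------------------------------

def test_planarity_trivial_cases():
    coplanar = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0.0]])
    assert planarity(coplanar).rmsd == pytest.approx(0.0, abs=1e-12)
    grid = np.array([[x, y, z] for x in (0, 4.0) for y in (0, 4.0)
                     for z in (-1.0, 1.0)])
    assert planarity(grid).rmsd == pytest.approx(1.0)


def test_planarity_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        planarity(np.array([[0, 0, 0], [1, 1, 1.0]]))
    line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        planarity(line)


def test_planarity_matches_grid_search_oracle():
    rng = np.random.default_rng(11)
    cloud = rng.normal(0, 2.0, (20, 3)) * np.array([1.0, 1.0, 0.3])
    ours = planarity(cloud).rmsd
    oracle = planarity_grid_search(cloud)
    assert abs(ours - oracle) < 1e-3
    assert ours <= oracle + 1e-12  # SVD is the exact minimiser


def test_planarity_never_increases_moving_atom_onto_plane():
    rng = np.random.default_rng(13)
    cloud = rng.normal(0, 2.0, (15, 3)) * np.array([1.0, 1.0, 0.3])
    res = planarity(cloud)
    # project the farthest atom onto the fitted plane
    dist = (cloud - cloud.mean(axis=0)) @ res.normal
    i = int(np.argmax(np.abs(dist)))
    moved = cloud.copy()
    moved[i] = moved[i] - (moved[i] @ res.normal - res.offset) * res.normal
    assert planarity(moved).rmsd <= res.rmsd + 1e-12


def test_planarity_of_sphere_cap_matches_closed_form():
    # dense spherical cap of half-angle alpha: rmsd from the best plane has
    # a closed form via the moments of z = R cos(theta) on the cap
    R, alpha = 10.0, 0.6
    n = 4000
    k = np.arange(n, dtype=float)
    # uniform cap sampling in cos(theta)
    c = 1.0 - (k + 0.5) / n * (1.0 - np.cos(alpha))
    phi = np.pi * (1.0 + 5.0 ** 0.5) * k
    s = np.sqrt(1.0 - c * c)
    pts = R * np.column_stack([s * np.cos(phi), s * np.sin(phi), c])
    ours = planarity(pts).rmsd
    # E[z] and Var[z] for z uniform on [R cos(alpha), R]
    half = R * (1.0 - np.cos(alpha)) / 2.0
    expected = half / np.sqrt(3.0)
    assert ours == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# rigid-motion invariance of all three descriptors
# ---------------------------------------------------------------------------

def test_descriptors_rigid_motion_invariant():
    rng = np.random.default_rng(21)
    pts = rng.uniform(0, 14, (60, 3))
    radii = np.full(60, 1.7)
    vols = rng.uniform(10, 30, 60)
    theta = 0.9
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    shift = np.array([7.0, -2.0, 4.0])
    moved = pts @ rot.T + shift

    cx1 = protrusion_bruteforce(pts, vols)
    cx2 = protrusion_bruteforce(moved, vols)
    np.testing.assert_allclose(cx1, cx2, rtol=1e-6)

    atoms1 = _as_residues([_carbon(p, volume=v) for p, v in zip(pts, vols)])
    atoms2 = _as_residues([_carbon(p, volume=v) for p, v in zip(moved, vols)])
    out1 = protrusion_index(atoms1)
    out2 = protrusion_index(atoms2)
    np.testing.assert_allclose(out1.per_atom_cx, out2.per_atom_cx, rtol=1e-6)

    # roughness rests on sampled SASA: invariance holds to sampling noise,
    # which shrinks with the point count
    probes = tuple(np.round(np.arange(0.5, 4.01, 0.5), 10))
    s1 = roughness(pts, radii, probes=probes, n_points=960).slope
    s2 = roughness(moved, radii, probes=probes, n_points=960).slope
    assert s1 == pytest.approx(s2, rel=0.02)

    assert planarity(pts).rmsd == pytest.approx(planarity(moved).rmsd,
                                                rel=1e-6)
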