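"""Composition, propensity, contact detection and contact statistics."""

import numpy as np
import pandas as pd
import pytest

import dimerface as df
from dimerface import data
from dimerface.contacts import (contact_frequency, contact_score,
                                ContactRecord, find_contacts, composition,
                                propensity)
from dimerface.sasa import classify_regions

from oracles import contacts_bruteforce


def _assignment(region_by_key):
    rm, rc = {}, {}
    for key, region in region_by_key.items():
        rm[key], rc[key] = {
            "interior": (0.1, 0.1), "surface": (0.6, 0.6),
            "core": (0.6, 0.1), "rim": (0.6, 0.4), "support": (0.2, 0.1),
        }[region]
    return classify_regions(rm, rc)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_composition_single_structure_pure_region():
    keys = [("A", i, "") for i in range(4)]
    a = _assignment({k: "surface" for k in keys})
    table = composition([(a, {k: "LEU" for k in keys})])
    assert table.loc["surface", "LEU"] == pytest.approx(100.0)
    assert table.loc["surface"].drop("LEU").sum() == pytest.approx(0.0)


def test_composition_averages_per_structure_percentages():
    keys = [("A", i, "") for i in range(4)]
    a = _assignment({k: "surface" for k in keys})
    s1 = (a, {k: "LEU" for k in keys})
    s2 = (a, {k: "ALA" for k in keys})
    table = composition([s1, s2])
    assert table.loc["surface", "LEU"] == pytest.approx(50.0)
    assert table.loc["surface", "ALA"] == pytest.approx(50.0)


def test_composition_recovers_generator_ground_truth():
    comp = ["LEU"] * 5 + ["ALA"] * 3 + ["SER"] * 2
    # 5x4 grid: 20 residues per monomer = exactly two composition cycles
    dimer, truth = df.make_planar_slab_dimer(n_x=5, n_y=4, seed=9,
                                             composition=comp)
    keys = [r.key for r in dimer.all_residues()]
    a = _assignment({k: "surface" for k in keys})
    types = {r.key: r.res_type for r in dimer.all_residues()}
    table = composition([(a, types)])
    assert table.loc["surface", "LEU"] == pytest.approx(50.0)
    assert table.loc["surface", "ALA"] == pytest.approx(30.0)
    assert table.loc["surface", "SER"] == pytest.approx(20.0)
    assert table.loc["surface"].sum() == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# propensity
# ---------------------------------------------------------------------------

def test_propensity_identical_profiles_give_one():
    k_sasa = {("A", 1, ""): 50.0, ("A", 2, ""): 30.0}
    k_types = {("A", 1, ""): "LEU", ("A", 2, ""): "ALA"}
    m_sasa = {("B", 1, ""): 100.0, ("B", 2, ""): 60.0}
    m_types = {("B", 1, ""): "LEU", ("B", 2, ""): "ALA"}
    p = propensity(k_sasa, k_types, m_sasa, m_types)
    assert p["LEU"] == pytest.approx(1.0)
    assert p["ALA"] == pytest.approx(1.0)


def test_propensity_hand_fixture_and_edge_cases():
    # type i: 300 of 400 A^2 in k, 100 of 400 in m -> P = 3
    k_sasa = {("A", 1, ""): 300.0, ("A", 2, ""): 100.0}
    k_types = {("A", 1, ""): "TRP", ("A", 2, ""): "GLY"}
    m_sasa = {("B", 1, ""): 100.0, ("B", 2, ""): 300.0}
    m_types = {("B", 1, ""): "TRP", ("B", 2, ""): "GLY"}
    p = propensity(k_sasa, k_types, m_sasa, m_types)
    assert p["TRP"] == pytest.approx(3.0)
    # absent from k, present in m -> 0; absent from m -> missing (NaN)
    assert p["GLY"] == pytest.approx(1.0 / 3.0)
    assert p["LEU"] != p["LEU"]  # NaN
    m_only = propensity(m_sasa, m_types, k_sasa, k_types)
    assert m_only["TRP"] == pytest.approx(1.0 / 3.0)


def test_propensity_reciprocity():
    rng = np.random.default_rng(5)
    types = list(data.AMINO_ACIDS[:6])
    k_sasa = {("A", i, ""): float(rng.uniform(10, 100)) for i in range(12)}
    k_types = {k: types[i % 6] for i, k in enumerate(k_sasa)}
    m_sasa = {("B", i, ""): float(rng.uniform(10, 100)) for i in range(12)}
    m_types = {k: types[(i + 1) % 6] for i, k in enumerate(m_sasa)}
    p_km = propensity(k_sasa, k_types, m_sasa, m_types)
    p_mk = propensity(m_sasa, m_types, k_sasa, k_types)
    for t in types:
        assert p_km[t] * p_mk[t] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def _gly(chain, seq, x, z):
    return df.Residue(chain, seq, "GLY", [
        df.Atom("N", "N", (x - 1.2, 0.0, z)),
        df.Atom("CA", "C", (x, 0.0, z)),
        df.Atom("C", "C", (x + 1.2, 0.0, z)),
        df.Atom("O", "O", (x + 1.2, 1.2, z)),
    ])


def test_backbone_contact_at_5p9_but_not_sidechain_at_4p5():
    a = _gly("A", 1, 0.0, 0.0)
    b = _gly("B", 1, 0.0, 5.9)
    recs = find_contacts([a], [b])
    assert len(recs) == 1 and recs[0].contact_class == "bb-bb"

    # side chains 4.5 A apart, backbones far: no contact (4.5 > 4)
    sc_a = df.Residue("A", 1, "ALA", [
        df.Atom("CA", "C", (0, 0, 0)), df.Atom("CB", "C", (0, 0, 1.5))])
    sc_b = df.Residue("B", 1, "ALA", [
        df.Atom("CA", "C", (0, 0, 7.5)), df.Atom("CB", "C", (0, 0, 6.0))])
    assert find_contacts([sc_a], [sc_b]) == []
    # move side chains to 3.9 A: sc-sc contact appears
    sc_b2 = df.Residue("B", 1, "ALA", [
        df.Atom("CA", "C", (0, 0, 6.9)), df.Atom("CB", "C", (0, 0, 5.4))])
    recs = find_contacts([sc_a], [sc_b2])
    assert len(recs) == 1 and recs[0].contact_class == "sc-sc"


def test_contacts_match_bruteforce_oracle_on_slab(slab):
    dimer, _ = slab
    recs = find_contacts(dimer.monomer_a, dimer.monomer_b)
    ours = {(r.residue_a, r.residue_b) for r in recs}
    oracle = contacts_bruteforce(dimer.monomer_a, dimer.monomer_b)
    assert ours == oracle
    # symmetry under monomer swap
    swapped = find_contacts(dimer.monomer_b, dimer.monomer_a)
    assert {(r.residue_b, r.residue_a) for r in swapped} == ours


# ---------------------------------------------------------------------------
# contact frequency and score
# ---------------------------------------------------------------------------

def _rec(ta, tb, i):
    return ContactRecord(("A", i, ""), ta, ("B", i, ""), tb, "bb-bb", 5.0,
                         {"bb-bb": 5.0})


def test_contact_frequency_counts():
    recs = [_rec("LEU", "LEU", 1), _rec("LEU", "LEU", 2),
            _rec("LEU", "ALA", 3), _rec("ARG", "GLU", 4)]
    fm = contact_frequency(recs)
    assert fm.freq.loc["LEU", "LEU"] == pytest.approx(0.5)
    assert fm.freq.loc["LEU", "ALA"] == pytest.approx(0.25)
    assert fm.freq.loc["ALA", "LEU"] == pytest.approx(0.25)
    assert fm.freq.loc["ARG", "GLU"] == pytest.approx(0.25)
    # unordered-pair total is 1
    tri = np.triu(fm.freq.to_numpy())
    assert tri.sum() == pytest.approx(1.0)


def test_contact_frequency_single_pair_and_empty():
    fm = contact_frequency([_rec("TRP", "TRP", 1)] * 3)
    assert fm.freq.loc["TRP", "TRP"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        contact_frequency([])


def test_pair_law_recovery_within_multinomial_error():
    # generator draws 10,000 contacts from stated pair probabilities
    rng = np.random.default_rng(17)
    law = {("LEU", "LEU"): 0.5, ("LEU", "ALA"): 0.3, ("ARG", "GLU"): 0.2}
    pairs = list(law)
    n = 10_000
    counts = rng.multinomial(n, list(law.values()))
    recs = []
    i = 0
    for (ta, tb), c in zip(pairs, counts):
        for _ in range(c):
            i += 1
            recs.append(_rec(ta, tb, i))
    fm = contact_frequency(recs)
    for (ta, tb), p in law.items():
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(fm.freq.loc[ta, tb] - p) <= 3 * sigma


def test_contact_score_zero_when_observed_equals_expected():
    # two types, equal fractions; observed matches random pairing exactly
    recs = ([_rec("LEU", "LEU", i) for i in range(1)]
            + [_rec("ALA", "ALA", 10 + i) for i in range(1)]
            + [_rec("LEU", "ALA", 20 + i) for i in range(2)])
    fm = contact_frequency(recs)
    f = pd.Series(0.0, index=list(data.AMINO_ACIDS))
    f["LEU"] = f["ALA"] = 0.5
    sm = contact_score(fm, f)
    assert sm.score.loc["LEU", "LEU"] == pytest.approx(0.0)
    assert sm.score.loc["ALA", "ALA"] == pytest.approx(0.0)
    assert sm.score.loc["LEU", "ALA"] == pytest.approx(0.0)
    # plain-ratio mode: same cells are exactly 1
    sr = contact_score(fm, f, log2=False)
    assert sr.score.loc["LEU", "ALA"] == pytest.approx(1.0)


def test_contact_score_doubled_observed_is_log2_one():
    recs = ([_rec("LEU", "ALA", i) for i in range(2)]
            + [_rec("LEU", "LEU", 10)] + [_rec("ALA", "ALA", 20)])
    f = pd.Series(0.0, index=list(data.AMINO_ACIDS))
    f["LEU"] = f["ALA"] = 0.5
    fm = contact_frequency(recs)
    # observed LEU-ALA = 0.5 = expected: build a doubled-observed variant
    fm.freq.loc["LEU", "ALA"] = fm.freq.loc["ALA", "LEU"] = 1.0
    sm = contact_score(fm, f)
    assert sm.score.loc["LEU", "ALA"] == pytest.approx(1.0)


def test_contact_score_single_type_interface():
    recs = [_rec("LEU", "LEU", i) for i in range(4)]
    fm = contact_frequency(recs)
    f = pd.Series(0.0, index=list(data.AMINO_ACIDS))
    f["LEU"] = 1.0
    sm = contact_score(fm, f)
    assert sm.score.loc["LEU", "LEU"] == pytest.approx(0.0)
    assert np.isnan(sm.score.loc["ALA", "ALA"])


def test_score_converges_to_zero_under_random_pairing():
    # pairs drawn independently from the composition: S -> 0 as n grows
    rng = np.random.default_rng(23)
    types = ["LEU", "ALA", "SER", "GLU"]
    probs = [0.4, 0.3, 0.2, 0.1]
    f = pd.Series(0.0, index=list(data.AMINO_ACIDS))
    for t, p in zip(types, probs):
        f[t] = p
    max_abs = []
    for n in (500, 5_000, 50_000):
        draws = rng.choice(len(types), size=(n, 2), p=probs)
        recs = [_rec(types[a], types[b], i)
                for i, (a, b) in enumerate(draws)]
        sm = contact_score(contact_frequency(recs), f)
        vals = sm.score.loc[types, types].to_numpy()
        max_abs.append(np.nanmax(np.abs(vals)))
    assert max_abs[2] < max_abs[0]
    assert max_abs[2] < 0.1
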