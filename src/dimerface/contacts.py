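"""Residue composition, location propensities, and inter-monomer contacts.

Composition is reported as mean residue composition (%mrc): per-structure
percentages of each amino-acid type in a region, averaged over structures.
Propensity compares the SASA-weighted frequency of a residue type between
two locations.  Contacts between the two monomers are classified by the
closest heavy-atom distance of backbone/side-chain atom groups with
per-class thresholds (6 A bb-bb, 5 A bb-sc, 4 A sc-sc), and summarised as
a 20x20 observed-frequency matrix and a log2 observed/expected score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import data
from .model import Residue, ResidueKey
from .sasa import RegionAssignment

CONTACT_THRESHOLDS = {"bb-bb": 6.0, "bb-sc": 5.0, "sc-sc": 4.0}


@dataclass(slots=True)
class ContactRecord:
    residue_a: ResidueKey
    type_a: str
    residue_b: ResidueKey
    type_b: str
    contact_class: str               # primary class = smallest threshold passed
    min_distance: float              # A, of the primary class
    classes: dict[str, float]        # every passing class -> its min distance


@dataclass(slots=True)
class ContactFrequencyMatrix:
    freq: pd.DataFrame               # 20x20 symmetric, unordered pairs sum to 1
    counts: pd.DataFrame             # symmetric raw pair counts
    total: int


@dataclass(slots=True)
class ContactScoreMatrix:
    score: pd.DataFrame              # 20x20; NaN where observed count is 0
    expected: pd.DataFrame           # random-pairing expectation
    log2: bool


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition(assignments: list[tuple[RegionAssignment, dict[ResidueKey, str]]],
                ) -> pd.DataFrame:
    """Mean residue composition (%mrc) per region.

    ``assignments`` pairs each structure's region assignment with a
    residue -> res_type map.  Per structure and region, the percentage of
    each type is computed; %mrc averages these percentages over the
    structures that have a non-empty region.
    """
    if not assignments:
        raise ValueError("need at least one structure")
    rows = []
    for assignment, types in assignments:
        for region in ("interior", "surface", "core", "rim", "support"):
            keys = assignment.residues_in(region)
            if not keys:
                continue
            counts = pd.Series([types[k] for k in keys]).value_counts()
            pct = counts.reindex(data.AMINO_ACIDS, fill_value=0) / len(keys) * 100.0
            rows.append(pd.Series(pct, name=region))
    if not rows:
        raise ValueError("no populated regions in any structure")
    df = pd.DataFrame(rows)
    mrc = df.groupby(df.index).mean()
    return mrc[list(data.AMINO_ACIDS)]


# ---------------------------------------------------------------------------
# propensity
# ---------------------------------------------------------------------------

def propensity(k_sasa: dict[ResidueKey, float], k_types: dict[ResidueKey, str],
               m_sasa: dict[ResidueKey, float], m_types: dict[ResidueKey, str],
               weight: str = "sasa") -> pd.Series:
    """P(i_k/m): SASA-weighted frequency of type i in region k over region m.

    P = [sum SASA of type i in k / sum SASA in k] / [same ratio in m].
    Types absent from m have an undefined propensity and are reported as
    NaN rather than infinity; ``weight='count'`` switches to plain residue
    counting.
    """
    if not k_sasa or not m_sasa:
        raise ValueError("both regions must be non-empty")

    def _fractions(sasa: dict[ResidueKey, float],
                   types: dict[ResidueKey, str]) -> pd.Series:
        by_type = dict.fromkeys(data.AMINO_ACIDS, 0.0)
        tot = 0.0
        for key, area in sasa.items():
            w = 1.0 if weight == "count" else float(area)
            by_type[types[key]] += w
            tot += w
        if tot <= 0:
            raise ValueError("zero total SASA in a region")
        return pd.Series(by_type) / tot

    fk = _fractions(k_sasa, k_types)
    fm = _fractions(m_sasa, m_types)
    out = fk / fm
    out[fm == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _group_coords(res: Residue) -> dict[str, np.ndarray]:
    bb = [a.coords for a in res.atoms if a.is_backbone]
    sc = [a.coords for a in res.atoms if not a.is_backbone]
    out = {}
    if bb:
        out["bb"] = np.asarray(bb)
    if sc:
        out["sc"] = np.asarray(sc)
    return out


def find_contacts(monomer_a: list[Residue],
                  monomer_b: list[Residue],
                  thresholds: dict[str, float] | None = None,
                  ) -> list[ContactRecord]:
    """All cross-monomer residue contacts.

    For each residue pair the minimum heavy-atom distance is evaluated per
    class (backbone-backbone, backbone-sidechain in either direction,
    sidechain-sidechain); the pair is a contact when any class beats its
    threshold.  One record per residue pair; its primary class is the one
    with the smallest threshold among those passing.
    """
    thr = thresholds or CONTACT_THRESHOLDS
    max_thr = max(thr.values())
    records: list[ContactRecord] = []
    groups_b = [(r, _group_coords(r), r.coord_array()) for r in monomer_b]
    for ra in monomer_a:
        ga = _group_coords(ra)
        ca = ra.coord_array()
        lo_a = ca.min(axis=0) - max_thr
        hi_a = ca.max(axis=0) + max_thr
        for rb, gb, cb in groups_b:
            # cheap bounding-box rejection
            if np.any(cb.max(axis=0) < lo_a) or np.any(cb.min(axis=0) > hi_a):
                continue
            passing: dict[str, float] = {}
            for cls, (xa, xb) in {
                "bb-bb": ("bb", "bb"), "bb-sc": ("bb", "sc"),
                "sc-sc": ("sc", "sc"),
            }.items():
                dmins = []
                pairs = [(xa, xb)] if cls != "bb-sc" else [("bb", "sc"), ("sc", "bb")]
                for pa, pb in pairs:
                    if pa in ga and pb in gb:
                        dmins.append(float(cdist(ga[pa], gb[pb]).min()))
                if dmins and min(dmins) <= thr[cls]:
                    passing[cls] = min(dmins)
            if passing:
                primary = min(passing, key=lambda c: thr[c])
                records.append(ContactRecord(
                    ra.key, ra.res_type, rb.key, rb.res_type,
                    primary, passing[primary], passing))
    return records


def contact_frequency(records: list[ContactRecord]) -> ContactFrequencyMatrix:
    """Observed contact frequency C_ij over unordered residue-type pairs.

    Each residue pair counts once; C_ij = (count of {i,j} contacts in
    either orientation) / total contacts.  The matrix is symmetric and the
    unordered-pair (upper-triangle) sum is 1.
    """
    if not records:
        raise ValueError("no contacts to summarise")
    aa = list(data.AMINO_ACIDS)
    idx = {r: i for i, r in enumerate(aa)}
    counts = np.zeros((20, 20))
    for rec in records:
        i, j = idx[rec.type_a], idx[rec.type_b]
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    total = len(records)
    freq = counts / total
    return ContactFrequencyMatrix(
        pd.DataFrame(freq, index=aa, columns=aa),
        pd.DataFrame(counts, index=aa, columns=aa),
        total,
    )


def contact_score(freq: ContactFrequencyMatrix,
                  interface_fractions: pd.Series,
                  log2: bool = True) -> ContactScoreMatrix:
    """Observed-over-expected contact score S_ij.

    Expected frequency under random pairing from the interface residue
    composition f: C_exp,ij = 2 f_i f_j off-diagonal, f_i^2 on-diagonal.
    Default score is log2(C_ij / C_exp,ij), so S = 0 means random
    association; ``log2=False`` reports the plain ratio.  Cells with no
    observed contacts are NaN (missing), not -inf.
    """
    f = interface_fractions.reindex(data.AMINO_ACIDS, fill_value=0.0)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("interface composition fractions must sum to 1")
    fv = f.to_numpy()
    exp = 2.0 * np.outer(fv, fv)
    np.fill_diagonal(exp, fv ** 2)
    obs = freq.freq.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((obs > 0) & (exp > 0), obs / np.where(exp > 0, exp, 1.0),
                         np.nan)
        score = np.log2(ratio) if log2 else ratio
    aa = list(data.AMINO_ACIDS)
    return ContactScoreMatrix(
        pd.DataFrame(score, index=aa, columns=aa),
        pd.DataFrame(exp, index=aa, columns=aa),
        log2,
    )


def interface_composition_fractions(assignment: RegionAssignment,
                                    types: dict[ResidueKey, str],
                                    regions: tuple[str, ...] = ("core", "rim", "support"),
                                    ) -> pd.Series:
    """Residue-type fractions of the pooled interface residues."""
    keys = assignment.residues_in(*regions)
    if not keys:
        raise ValueError("empty interface")
    counts = pd.Series([types[k] for k in keys]).value_counts()
    return counts.reindex(data.AMINO_ACIDS, fill_value=0) / len(keys)
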