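"""End-to-end per-structure analysis and per-category aggregation.

``run_structure`` executes the full per-dimer chain: clean, split, SASA in
monomer and complex, five-region classification, compact-interface filter,
surface patches, shape descriptors, inter-monomer contacts.  ``aggregate``
pools descriptor tables across structures and produces the category-level
report: composition, propensities, contact matrices, and Bayesian effect
sizes (surface vs core, surface vs rim) per descriptor and environment.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import contacts as contacts_mod
from . import data
from .bayes import EffectSizeConfig, EffectSizeResult, TwoGroupSample, effect_size
from .descriptors import (CX_SPHERE_RADIUS, ROUGHNESS_PROBE_GRID,
                          planarity, protrusion_index, roughness)
from .model import Dimer, MembraneSlab, Residue, clean_structure, flatten, parse_structure
from .patches import DEFAULT_ANGLE_CUTOFF, PATCH_SIZES, all_patches, solvent_vectors
from .sasa import (DEFAULT_DELTA_TOL, DEFAULT_N_POINTS, DEFAULT_PROBE,
                   DEFAULT_RASA_CUTOFF, MIN_BURIED_BY_CATEGORY, RegionAssignment,
                   buried_surface_area, classify_regions, interface_size_filter,
                   relative_asa, shrake_rupley)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class CategoryConfig:
    """Per-category pipeline settings; defaults follow the analysis protocol."""

    category: str | None = None          # cytoplasmic_alpha | cytoplasmic_beta | membrane
    min_buried: int | None = None        # None -> category default (14/17/18), else 14
    probe: float = DEFAULT_PROBE
    n_points: int = DEFAULT_N_POINTS
    rasa_cutoff: float = DEFAULT_RASA_CUTOFF
    delta_tol: float = DEFAULT_DELTA_TOL
    patch_sizes: tuple[int, ...] = PATCH_SIZES
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF
    roughness_probes: tuple[float, ...] = ROUGHNESS_PROBE_GRID
    roughness_n_points: int = 240
    cx_radius: float = CX_SPHERE_RADIUS
    contact_thresholds: dict = field(
        default_factory=lambda: dict(contacts_mod.CONTACT_THRESHOLDS))
    score_log2: bool = True
    pooling_mode: str = "residues"       # or "structure_means"
    sampler: EffectSizeConfig = field(default_factory=EffectSizeConfig)
    seed: int = 0

    def resolved_min_buried(self) -> int:
        if self.min_buried is not None:
            return self.min_buried
        if self.category in MIN_BURIED_BY_CATEGORY:
            return MIN_BURIED_BY_CATEGORY[self.category]
        return MIN_BURIED_BY_CATEGORY["cytoplasmic_alpha"]


@dataclass(slots=True)
class StructureResult:
    structure_id: str
    table: pd.DataFrame
    contacts: pd.DataFrame
    assignment: RegionAssignment
    passed_filter: bool
    n_buried: int
    bsa: float
    contact_records: list = field(repr=False, default_factory=list)
    interface_fractions: pd.Series | None = field(repr=False, default=None)


def _patch_descriptor_columns(config: CategoryConfig) -> list[str]:
    cols = []
    for n in config.patch_sizes:
        cols += [f"roughness_patch{n}", f"planarity_patch{n}"]
    return cols


def run_structure(source: str | Dimer,
                  config: CategoryConfig | None = None,
                  slab: MembraneSlab | None = None) -> StructureResult:
    """Run the whole per-dimer analysis; returns the flat descriptor table.

    Structures failing the compact-interface filter are still fully
    analysed and returned with ``passed_filter=False`` so the caller can
    report exclusions rather than crash.
    """
    from .model import assign_environment

    cfg = config or CategoryConfig()
    t0 = time.perf_counter()
    if isinstance(source, Dimer):
        dimer = clean_structure(source)
    else:
        dimer = clean_structure(parse_structure(source))
    env = assign_environment(dimer, slab)

    # SASA: complex, then each monomer in isolation
    all_res = dimer.all_residues()
    sasa_complex = shrake_rupley(all_res, probe=cfg.probe, n_points=cfg.n_points)
    sasa_monomer_vals = {}
    monomer_sasa_totals = []
    rasa_m: dict = {}
    for residues in dimer.monomers:
        s = shrake_rupley(residues, probe=cfg.probe, n_points=cfg.n_points)
        sasa_monomer_vals.update(s.per_residue)
        monomer_sasa_totals.append(s.total)
        rasa_m.update(relative_asa(s, residues))

    rasa_c = relative_asa(sasa_complex, all_res)
    assignment = classify_regions(rasa_m, rasa_c,
                                  cutoff=cfg.rasa_cutoff, tol=cfg.delta_tol)
    passed, n_buried = interface_size_filter(assignment, cfg.resolved_min_buried())
    bsa = buried_surface_area(monomer_sasa_totals[0], monomer_sasa_totals[1],
                              sasa_complex.total)

    # per-monomer shape descriptors on the monomer-state surface
    cx: dict = {}
    patch_vals: dict[str, dict] = {c: {} for c in _patch_descriptor_columns(cfg)}
    for residues in dimer.monomers:
        surface = [r for r in residues if rasa_m[r.key] >= cfg.rasa_cutoff]
        arrays = flatten(residues)
        surface_keys = {r.key for r in surface}
        mask = np.array([arrays.residues[o].key in surface_keys
                         for o in arrays.owner])
        if mask.any():
            prot = protrusion_index(arrays, target_mask=mask, radius=cfg.cx_radius)
            cx.update(prot.per_residue_cx)
        if len(surface) < 11:
            logger.warning("%s: only %d surface residues in a monomer; "
                           "patch descriptors skipped", dimer.id, len(surface))
            continue
        sv = solvent_vectors(surface)
        patches = all_patches(surface, cfg.patch_sizes, sv, cfg.angle_cutoff)
        by_key = {r.key: r for r in surface}
        for n, plist in patches.items():
            for patch in plist:
                members = [by_key[k] for k in patch.members]
                parrays = flatten(members)
                try:
                    rr = roughness(parrays.coords, parrays.radii,
                                   probes=cfg.roughness_probes,
                                   n_points=cfg.roughness_n_points)
                    patch_vals[f"roughness_patch{n}"][patch.center] = rr.roughness
                except ValueError:
                    pass
                try:
                    pl = planarity(parrays.coords)
                    patch_vals[f"planarity_patch{n}"][patch.center] = pl.rmsd
                except ValueError:
                    pass

    records = contacts_mod.find_contacts(dimer.monomer_a, dimer.monomer_b,
                                         cfg.contact_thresholds)
    types = {r.key: r.res_type for r in all_res}
    try:
        iface_frac = contacts_mod.interface_composition_fractions(assignment, types)
    except ValueError:
        iface_frac = None

    rows = []
    for res in all_res:
        k = res.key
        row = {
            "structure_id": dimer.id, "chain": k[0], "seq_id": k[1],
            "icode": k[2], "res_type": res.res_type, "environment": env[k],
            "region": assignment.region[k],
            "sasa_monomer": sasa_monomer_vals[k],
            "sasa_complex": sasa_complex.per_residue[k],
            "rasa_monomer": assignment.rasa_monomer[k],
            "rasa_complex": assignment.rasa_complex[k],
            "delta_rasa": assignment.delta_rasa[k],
            "cx": cx.get(k, np.nan),
        }
        for col in _patch_descriptor_columns(cfg):
            row[col] = patch_vals[col].get(k, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)

    contact_rows = [{
        "chain_a": r.residue_a[0], "seq_a": r.residue_a[1], "type_a": r.type_a,
        "chain_b": r.residue_b[0], "seq_b": r.residue_b[1], "type_b": r.type_b,
        "contact_class": r.contact_class,
        "min_distance": round(r.min_distance, 4),
    } for r in records]
    contact_table = pd.DataFrame(
        contact_rows, columns=["chain_a", "seq_a", "type_a", "chain_b",
                               "seq_b", "type_b", "contact_class",
                               "min_distance"])
    logger.info("%s: %d residues, %d contacts, buried=%d, filter=%s (%.2fs)",
                dimer.id, len(table), len(records), n_buried,
                "pass" if passed else "FAIL", time.perf_counter() - t0)
    return StructureResult(dimer.id, table, contact_table, assignment,
                           passed, n_buried, bsa, records, iface_frac)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

REGION_PAIRS = (("core", "surface"), ("rim", "surface"))


@dataclass(slots=True)
class AggregateReport:
    effect_sizes: pd.DataFrame
    composition: pd.DataFrame
    propensity: pd.DataFrame
    contact_frequency: pd.DataFrame | None
    contact_score: pd.DataFrame | None
    excluded: list[str]
    notices: list[str]


def _descriptor_columns(config: CategoryConfig) -> list[str]:
    return ["sasa_monomer", "cx"] + _patch_descriptor_columns(config)


def aggregate(results: list[StructureResult],
              config: CategoryConfig | None = None) -> AggregateReport:
    """Category-level report over the structures passing the interface filter.

    Effect sizes compare each interface region's descriptor distribution
    against the non-interface surface (b > 0 means the interface region
    has the larger mean); residues are pooled across structures by default,
    with a per-structure-means mode in the config.
    """
    cfg = config or CategoryConfig()
    if not results:
        raise ValueError("no structure results to aggregate")
    excluded = [r.structure_id for r in results if not r.passed_filter]
    kept = [r for r in results if r.passed_filter]
    notices: list[str] = []
    if not kept:
        notices.append("no structure passed the interface filter; "
                       "aggregating all structures instead")
        kept = list(results)

    tables = pd.concat([r.table for r in kept], ignore_index=True)
    descriptor_cols = [c for c in _descriptor_columns(cfg) if c in tables] + [
        c for c in tables.columns
        if c.startswith(("roughness_patch", "planarity_patch"))
        and c not in _descriptor_columns(cfg)]

    # --- Bayesian effect sizes per descriptor x region pair x environment
    es_rows = []
    comparison_idx = 0
    for environment in sorted(tables["environment"].unique()):
        sub = tables[tables["environment"] == environment]
        for desc in descriptor_cols:
            for reg_k, reg_m in REGION_PAIRS:
                comparison_idx += 1
                if cfg.pooling_mode == "structure_means":
                    g1 = sub[sub.region == reg_k].groupby("structure_id")[desc].mean()
                    g2 = sub[sub.region == reg_m].groupby("structure_id")[desc].mean()
                    v1, v2 = g1.dropna().to_numpy(), g2.dropna().to_numpy()
                else:
                    v1 = sub.loc[sub.region == reg_k, desc].dropna().to_numpy()
                    v2 = sub.loc[sub.region == reg_m, desc].dropna().to_numpy()
                if len(v1) < 2 or len(v2) < 2 or (np.std(v1) == 0 and np.std(v2) == 0):
                    notices.append(
                        f"skipped {desc} {reg_k}-vs-{reg_m} ({environment}): "
                        f"insufficient data (n={len(v1)}/{len(v2)})")
                    continue
                scfg = replace(cfg.sampler,
                               seed=(cfg.seed * 1000 + comparison_idx) % (2 ** 31))
                res = effect_size(TwoGroupSample(reg_k, reg_m, v1, v2), scfg)
                es_rows.append({
                    "environment": environment, "descriptor": desc,
                    "region_1": reg_k, "region_2": reg_m,
                    "b_mean": res.b_mean, "hdi_low": res.hdi_low,
                    "hdi_high": res.hdi_high, "n1": res.n1, "n2": res.n2,
                    "ess": res.ess, "converged": res.converged,
                })
    effect_sizes = pd.DataFrame(es_rows, columns=[
        "environment", "descriptor", "region_1", "region_2", "b_mean",
        "hdi_low", "hdi_high", "n1", "n2", "ess", "converged"])

    # --- composition (%mrc)
    comp_inputs = []
    for r in kept:
        types = dict(zip(zip(r.table.chain, r.table.seq_id, r.table.icode),
                         r.table.res_type))
        comp_inputs.append((r.assignment, types))
    comp = contacts_mod.composition(comp_inputs)

    # --- propensities (monomer-state SASA weighting)
    prop = _propensities(kept)

    # --- pooled contact statistics
    all_records = [rec for r in kept for rec in r.contact_records]
    cfreq = cscore = None
    if all_records:
        fmat = contacts_mod.contact_frequency(all_records)
        frac = _pooled_interface_fractions(kept)
        if frac is not None:
            smat = contacts_mod.contact_score(fmat, frac, log2=cfg.score_log2)
            cscore = smat.score
        cfreq = fmat.freq
    else:
        notices.append("no inter-monomer contacts found")

    return AggregateReport(effect_sizes, comp, prop, cfreq, cscore,
                           excluded, notices)


def _propensities(kept: list[StructureResult]) -> pd.DataFrame:
    pairs = {
        "interface/surface": (("core", "rim", "support"), ("surface",)),
        "rim/surface": (("rim",), ("surface",)),
        "core/surface": (("core",), ("surface",)),
        "support/interior": (("support",), ("interior",)),
    }
    cols = {}
    for name, (k_regions, m_regions) in pairs.items():
        k_sasa, k_types, m_sasa, m_types = {}, {}, {}, {}
        for r in kept:
            for _, row in r.table.iterrows():
                key = (row.structure_id, row.chain, row.seq_id, row.icode)
                if row.region in k_regions:
                    k_sasa[key] = row.sasa_monomer
                    k_types[key] = row.res_type
                elif row.region in m_regions:
                    m_sasa[key] = row.sasa_monomer
                    m_types[key] = row.res_type
        if not k_sasa or not m_sasa:
            cols[name] = pd.Series(np.nan, index=list(data.AMINO_ACIDS))
            continue
        cols[name] = contacts_mod.propensity(k_sasa, k_types, m_sasa, m_types)
    return pd.DataFrame(cols)


def _pooled_interface_fractions(kept: list[StructureResult]) -> pd.Series | None:
    counts = pd.Series(0.0, index=list(data.AMINO_ACIDS))
    total = 0
    for r in kept:
        iface = r.table[r.table.region.isin(("core", "rim", "support"))]
        vc = iface.res_type.value_counts()
        counts = counts.add(vc.reindex(counts.index, fill_value=0), fill_value=0)
        total += len(iface)
    if total == 0:
        return None
    return counts / total
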