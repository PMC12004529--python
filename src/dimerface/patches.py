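"""Solvent vectors and contiguous surface patches.

A surface patch is a central surface residue plus its n nearest surface
neighbours whose outward solvent vectors are roughly consistent with the
centre's (angle below a cutoff, 110 degrees by default).  Solvent vectors
point away from the local centre of mass, i.e. toward the solvent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import data
from .model import Residue, ResidueKey

logger = logging.getLogger(__name__)

DEFAULT_ANGLE_CUTOFF = 110.0   # degrees, strict upper bound
N_COM_NEIGHBORS = 10           # neighbours pooled into the local centre of mass
PATCH_SIZES = (3, 9, 15, 17, 20)


@dataclass(slots=True)
class SolventVectors:
    """Per-residue outward unit vectors V_s with their construction data."""

    vectors: dict[ResidueKey, np.ndarray]     # unit V_s
    local_com: dict[ResidueKey, np.ndarray]   # C_m of residue + neighbours
    excluded: set[ResidueKey]                 # |V_i| ~ 0, no defined vector


@dataclass(slots=True)
class Patch:
    center: ResidueKey
    members: list[ResidueKey]      # includes center, centre first
    n: int                         # requested neighbour count
    undersized: bool = False

    def __len__(self) -> int:
        return len(self.members)


def _ca_positions(residues: list[Residue]) -> dict[ResidueKey, np.ndarray]:
    return {r.key: r.ca_or_center() for r in residues}


def solvent_vectors(surface_residues: list[Residue],
                    n_neighbors: int = N_COM_NEIGHBORS) -> SolventVectors:
    """Outward solvent vector for every surface residue of one monomer.

    For each residue, its ``n_neighbors`` nearest surface residues (Calpha
    distance) are pooled; C_m is the all-atom mass-weighted centre of the
    pooled residues, V_i runs from the residue's Calpha to C_m, and
    V_s = -V_i normalised.  Residues with |V_i| below 1e-6 A get no vector
    and are excluded from serving as patch centres.
    """
    if len(surface_residues) < n_neighbors + 1:
        raise ValueError(
            f"need at least {n_neighbors + 1} surface residues, "
            f"got {len(surface_residues)}")
    ca = _ca_positions(surface_residues)
    keys = [r.key for r in surface_residues]
    pos = np.array([ca[k] for k in keys])
    by_key = {r.key: r for r in surface_residues}

    vectors: dict[ResidueKey, np.ndarray] = {}
    coms: dict[ResidueKey, np.ndarray] = {}
    excluded: set[ResidueKey] = set()
    for i, key in enumerate(keys):
        d = np.linalg.norm(pos - pos[i], axis=1)
        order = sorted(range(len(keys)), key=lambda j: (d[j], keys[j]))
        chosen = [keys[j] for j in order[:n_neighbors + 1]]  # self included
        if key not in chosen:
            chosen[-1] = key
        masses, weighted = 0.0, np.zeros(3)
        for ck in chosen:
            for a in by_key[ck].atoms:
                m = data.atomic_mass(a.element)
                masses += m
                weighted += m * a.xyz
        com = weighted / masses
        v_i = com - pos[i]
        norm = float(np.linalg.norm(v_i))
        coms[key] = com
        if norm < 1e-6:
            logger.warning("undefined solvent vector for %s (|V_i| ~ 0)", key)
            excluded.add(key)
            continue
        vectors[key] = -v_i / norm
    return SolventVectors(vectors, coms, excluded)


def build_patch(center: Residue, n: int, surface_residues: list[Residue],
                sv: SolventVectors,
                angle_cutoff: float = DEFAULT_ANGLE_CUTOFF) -> Patch:
    """Patch of the ``n`` nearest angle-consistent surface neighbours.

    Candidates are scanned in order of increasing Calpha distance from the
    centre (ties broken by residue key); a candidate joins the patch when
    the angle between its solvent vector and the centre's is strictly
    below ``angle_cutoff`` degrees.  Rejected candidates are skipped, not
    scan-terminating.  When fewer than n candidates qualify the patch is
    returned undersized and flagged.
    """
    if center.key not in sv.vectors:
        raise ValueError(f"centre {center.key} has no solvent vector")
    if n < 0:
        raise ValueError("patch size must be >= 0")
    v0 = sv.vectors[center.key]
    c0 = center.ca_or_center()
    cos_cut = np.cos(np.radians(angle_cutoff))
    cands = []
    for res in surface_residues:
        if res.key == center.key or res.key not in sv.vectors:
            continue
        cands.append((float(np.linalg.norm(res.ca_or_center() - c0)), res.key))
    cands.sort()
    members = [center.key]
    for _, key in cands:
        if len(members) - 1 >= n:
            break
        # strict inequality: angle == cutoff is excluded
        if float(np.dot(sv.vectors[key], v0)) > cos_cut + 1e-12:
            members.append(key)
    return Patch(center.key, members, n, undersized=len(members) - 1 < n)


def all_patches(surface_residues: list[Residue],
                sizes: tuple[int, ...] = PATCH_SIZES,
                sv: SolventVectors | None = None,
                angle_cutoff: float = DEFAULT_ANGLE_CUTOFF,
                ) -> dict[int, list[Patch]]:
    """One patch per surface residue per size (overlapping by design)."""
    if sv is None:
        sv = solvent_vectors(surface_residues)
    out: dict[int, list[Patch]] = {}
    for n in sizes:
        out[n] = [build_patch(res, n, surface_residues, sv, angle_cutoff)
                  for res in surface_residues if res.key in sv.vectors]
    return out
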