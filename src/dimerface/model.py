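"""Structure model: atoms, residues, dimers, and membrane slabs.

A :class:`Dimer` is the cleaned, heavy-atom representation of a two-chain
homodimer.  Parsing goes through gemmi; after :func:`clean_structure` only
the 20 standard amino acids remain, hydrogens and hetero groups are gone,
and every atom carries a van der Waals radius and a reference volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import data

logger = logging.getLogger(__name__)

#: Internal residue key: (chain_id, seq_id, insertion_code).
ResidueKey = tuple[str, int, str]


class NotADimerError(ValueError):
    """Raised when a structure does not contain exactly >=2 usable chains."""


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


@dataclass(frozen=True, slots=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = data.DEFAULT_VDW_RADIUS
    ref_volume: float = data.FLAT_ATOM_VOLUME

    @property
    def is_backbone(self) -> bool:
        return self.name in data.BACKBONE_ATOMS

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(slots=True)
class Residue:
    chain_id: str
    seq_id: int
    res_type: str
    atoms: list[Atom]
    icode: str = ""

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def backbone(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_backbone]

    @property
    def side_chain(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def ca_or_center(self) -> np.ndarray:
        """Calpha position, or the geometric center when Calpha is absent."""
        ca = self.atom("CA")
        if ca is not None:
            return ca.xyz
        logger.debug("residue %s has no CA; using geometric center", self.key)
        return self.coord_array().mean(axis=0)

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def center_of_mass(self) -> np.ndarray:
        m = np.array([data.atomic_mass(a.element) for a in self.atoms])
        return (self.coord_array() * m[:, None]).sum(axis=0) / m.sum()


@dataclass(slots=True)
class Dimer:
    monomer_a: list[Residue]
    monomer_b: list[Residue]
    id: str = ""

    @property
    def monomers(self) -> tuple[list[Residue], list[Residue]]:
        return (self.monomer_a, self.monomer_b)

    def all_residues(self) -> list[Residue]:
        return list(self.monomer_a) + list(self.monomer_b)

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.all_residues()}


@dataclass(frozen=True, slots=True)
class MembraneSlab:
    """z-boundaries of the hydrophobic membrane slab (OPM frame)."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("z_lower must be < z_upper")

    def contains(self, z: float) -> bool:
        return self.z_lower <= z <= self.z_upper


# ---------------------------------------------------------------------------
# flattened numeric views
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AtomArrays:
    """Flat numeric view over the atoms of a residue list."""

    atoms: list[Atom]
    coords: np.ndarray          # (n, 3)
    radii: np.ndarray           # (n,)
    volumes: np.ndarray         # (n,)
    owner: np.ndarray           # (n,) index into `residues`
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.atoms)


def flatten(residues: list[Residue]) -> AtomArrays:
    atoms: list[Atom] = []
    owner: list[int] = []
    for i, res in enumerate(residues):
        atoms.extend(res.atoms)
        owner.extend([i] * len(res.atoms))
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    volumes = np.array([a.ref_volume for a in atoms], dtype=float)
    return AtomArrays(atoms, coords, radii, volumes,
                      np.asarray(owner, dtype=int), list(residues))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties alphabetically."""
    best: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = at
            continue
        if (at.occ, _altloc_rank(at)) > (prev.occ, _altloc_rank(prev)):
            best[at.name] = at
    return list(best.values())


def _altloc_rank(at: gemmi.Atom) -> float:
    # Later in the alphabet loses, so rank descending: '' > 'A' > 'B' ...
    loc = at.altloc if at.altloc else " "
    return -ord(loc)


def parse_structure(path: str, fmt: str = "pdb") -> Dimer:
    """Read model 1 of a PDB file into a :class:`Dimer`.

    Chains are mapped to monomers a/b in file order; altlocs are resolved
    (highest occupancy, tie broken alphabetically); hetero groups are kept
    for :func:`clean_structure` to strip.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported format: {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]

    chains: list[list[Residue]] = []
    for chain in model:
        residues: list[Residue] = []
        seen: set[ResidueKey] = set()
        for gres in chain:
            seq = gres.seqid.num
            icode = (gres.seqid.icode or " ").strip()
            key = (chain.name, seq, icode)
            if key in seen:
                # duplicate residue record: keep the first
                continue
            seen.add(key)
            atoms: list[Atom] = []
            names_seen: set[str] = set()
            for gat in _resolve_altlocs(gres):
                if gat.name in names_seen:
                    continue
                names_seen.add(gat.name)
                el = gat.element.name.upper()
                atoms.append(Atom(
                    name=gat.name,
                    element=el,
                    coords=(gat.pos.x, gat.pos.y, gat.pos.z),
                    occupancy=gat.occ,
                    altloc=gat.altloc or "",
                    vdw_radius=data.vdw_radius(el),
                    ref_volume=data.reference_volume(gres.name, gat.name, el),
                ))
            if atoms:
                residues.append(Residue(chain.name, seq, gres.name, atoms, icode))
        if residues:
            chains.append(residues)

    protein_chains = [c for c in chains if _looks_like_protein(c)]
    if len(protein_chains) < 2:
        raise NotADimerError(
            f"{path}: found {len(protein_chains)} protein chain(s), need 2")
    return Dimer(protein_chains[0], protein_chains[1],
                 id=str(path).rsplit("/", 1)[-1].removesuffix(".pdb"))


def _looks_like_protein(residues: list[Residue]) -> bool:
    n_aa = sum(r.res_type in data.AMINO_ACIDS
               or r.res_type in data.NONSTANDARD_MAP for r in residues)
    return n_aa >= 2


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_structure(d: Dimer) -> Dimer:
    """Strip waters/ligands/cofactors/hydrogens; standardize residues.

    Nonstandard residues with a bundled parent mapping (MSE etc.) are
    renamed; anything else non-standard is dropped with a warning.
    Duplicate atom records within a residue collapse to the first.
    """
    cleaned = []
    for residues in d.monomers:
        out: list[Residue] = []
        for res in residues:
            rt = res.res_type
            if rt in data.NONSTANDARD_MAP:
                rt = data.NONSTANDARD_MAP[res.res_type]
            elif rt not in data.AMINO_ACIDS:
                if rt not in ("HOH", "WAT", "DOD"):
                    logger.warning("dropping nonstandard residue %s %s",
                                   res.res_type, res.key)
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for a in res.atoms:
                if a.element in ("H", "D"):
                    continue
                if a.name in seen:
                    continue
                seen.add(a.name)
                if res.res_type != rt:
                    # remap volume for renamed residues (e.g. MSE SE -> MET SD)
                    name = "SD" if (res.res_type == "MSE" and a.name == "SE") else a.name
                    el = "S" if (res.res_type == "MSE" and a.element == "SE") else a.element
                    a = replace(a, name=name, element=el,
                                vdw_radius=data.vdw_radius(el),
                                ref_volume=data.reference_volume(rt, name, el))
                atoms.append(a)
            if atoms:
                out.append(Residue(res.chain_id, res.seq_id, rt, atoms, res.icode))
        cleaned.append(out)
    if not cleaned[0] or not cleaned[1]:
        raise NotADimerError(f"{d.id}: a chain was emptied by cleaning")
    return Dimer(cleaned[0], cleaned[1], id=d.id)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def assign_environment(d: Dimer,
                       slab: MembraneSlab | None = None) -> dict[ResidueKey, str]:
    """Label every residue 'lipid' or 'aqueous'.

    A residue is lipid iff its Calpha z-coordinate falls inside the slab
    (OPM frame, membrane normal along z).  Without a slab everything is
    aqueous.
    """
    env: dict[ResidueKey, str] = {}
    for res in d.all_residues():
        if slab is None:
            env[res.key] = "aqueous"
        else:
            if res.atom("CA") is None:
                logger.warning("residue %s has no CA; slab test uses its "
                               "geometric center", res.key)
            z = float(res.ca_or_center()[2])
            env[res.key] = "lipid" if slab.contains(z) else "aqueous"
    return env


def read_opm_slab(path: str) -> MembraneSlab | None:
    """Extract the membrane slab from OPM-style DUM pseudo-atoms.

    OPM files mark the two membrane planes with DUM residues; the slab is
    [min z, max z] over all DUM atoms.  Returns None when no DUM atoms are
    present.
    """
    zs: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")) and line[17:20].strip() == "DUM":
                zs.append(float(line[46:54]))
    if not zs:
        return None
    lo, hi = min(zs), max(zs)
    if not lo < hi:
        return None
    return MembraneSlab(lo, hi)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def to_gemmi(d: Dimer) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = d.id or "dimer"
    model = gemmi.Model("1")
    for residues in d.monomers:
        by_chain: dict[str, gemmi.Chain] = {}
        for res in residues:
            ch = by_chain.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                by_chain[res.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.res_type
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for a in res.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element.capitalize())
                gat.pos = gemmi.Position(*a.coords)
                gat.occ = a.occupancy
                gat.altloc = a.altloc or "\0"
                gres.add_atom(gat)
            ch.add_residue(gres)
        for ch in by_chain.values():
            model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(d: Dimer, path: str) -> None:
    """Write the dimer back out as PDB (debugging / fixture round-trips)."""
    to_gemmi(d).write_pdb(str(path))


def rigid_transform(d: Dimer, rotation: np.ndarray,
                    translation: np.ndarray) -> Dimer:
    """Apply a rigid motion (used by invariance tests and fixtures)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if not math.isclose(abs(float(np.linalg.det(R))), 1.0, rel_tol=1e-6):
        raise ValueError("rotation matrix must have |det| = 1")
    new_monomers = []
    for residues in d.monomers:
        out = []
        for res in residues:
            atoms = [replace(a, coords=tuple((R @ a.xyz) + t)) for a in res.atoms]
            out.append(Residue(res.chain_id, res.seq_id, res.res_type,
                               atoms, res.icode))
        new_monomers.append(out)
    return Dimer(new_monomers[0], new_monomers[1], id=d.id)
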