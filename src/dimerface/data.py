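"""Bundled reference tables.

All tables are plain dicts so a caller can pass an amended copy to any
function that consumes them; nothing in the package mutates them.

Provenance
----------
* van der Waals radii: Bondi (1964) per-element values.
* Maximum Gly-X-Gly SASA: theoretical maxima of Tien et al. (2013),
  PLoS ONE 8:e80635.  The relative-accessibility convention (SASA of X in
  an extended Gly-X-Gly tripeptide) is standard; any table of the same
  convention can be substituted.
* Reference atomic volumes: condensed class averages in the spirit of the
  Voronoi-volume surveys of Pontius et al. (1996); the flat 20.1 A^3 value
  is the classic single-volume convention and is the fallback for any atom
  the class rules do not cover.
* Hydrophobicity: Eisenberg normalized consensus scale (1984).
"""

from __future__ import annotations

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

#: Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

#: Atomic masses for center-of-mass calculations (heavy atoms only).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}
DEFAULT_ATOMIC_MASS = 12.011

#: Classic flat per-atom volume, A^3.
FLAT_ATOM_VOLUME = 20.1

#: Maximum SASA of residue X in a Gly-X-Gly tripeptide, A^2
#: (Tien et al. 2013, theoretical).
MAX_SASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Eisenberg normalized consensus hydrophobicity constants.
EISENBERG_HYDROPHOBICITY: dict[str, float] = {
    "ILE": 0.73, "PHE": 0.61, "VAL": 0.54, "LEU": 0.53, "TRP": 0.37,
    "MET": 0.26, "ALA": 0.25, "GLY": 0.16, "CYS": 0.04, "TYR": 0.02,
    "PRO": -0.07, "THR": -0.18, "SER": -0.26, "HIS": -0.40, "GLU": -0.62,
    "ASN": -0.64, "GLN": -0.69, "ASP": -0.72, "LYS": -1.10, "ARG": -1.76,
}


def hydrophobicity_order() -> list[str]:
    """The 20 residue types from most to least hydrophobic (Eisenberg)."""
    return sorted(AMINO_ACIDS, key=lambda r: -EISENBERG_HYDROPHOBICITY[r])


def is_hydrophobic(res_type: str) -> bool:
    """Two-class split by the sign of the hydrophobicity constant."""
    return EISENBERG_HYDROPHOBICITY[res_type] > 0.0


#: Common nonstandard residues mapped to their standard parent.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS", "KCX": "LYS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
}

# ---------------------------------------------------------------------------
# Reference Voronoi volumes (class averages, A^3)
# ---------------------------------------------------------------------------

_TERMINAL_METHYLS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "VAL": frozenset({"CG1", "CG2"}),
    "LEU": frozenset({"CD1", "CD2"}),
    "ILE": frozenset({"CG2", "CD1"}),
    "THR": frozenset({"CG2"}),
    "MET": frozenset({"CE"}),
}

_AROMATIC_RING: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
}

#: sp2 carbons of carboxyl / amide / guanidinium groups.
_POLAR_SP2_CARBON: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "ARG": frozenset({"CZ"}),
}

#: Branched sp3 CH carbons.
_CH_CARBON: dict[str, frozenset[str]] = {
    "VAL": frozenset({"CB"}),
    "LEU": frozenset({"CG"}),
    "ILE": frozenset({"CB"}),
    "THR": frozenset({"CB"}),
}

_CLASS_VOLUMES = {
    "bb_N": 13.9, "bb_CA": 13.2, "bb_CA_GLY": 22.4, "bb_C": 8.7, "bb_O": 16.4,
    "C_methyl": 36.7, "C_CH2": 23.2, "C_CH": 14.4, "C_aromatic": 18.3,
    "C_polar_sp2": 9.7, "N_side": 16.0, "O_side": 17.1, "S_side": 27.0,
}


def reference_volume(res_type: str, atom_name: str, element: str) -> float:
    """Mean Voronoi volume (A^3) for one heavy atom.

    Class-average lookup with the flat 20.1 A^3 fallback for anything the
    rules do not cover (unknown elements, ligand atoms left in by a caller
    skipping the cleaning step, synthetic pseudo-atoms).
    """
    element = element.upper()
    if atom_name in ("N", "C", "O"):
        return _CLASS_VOLUMES[f"bb_{atom_name}"]
    if atom_name == "CA" and element == "C":
        return _CLASS_VOLUMES["bb_CA_GLY" if res_type == "GLY" else "bb_CA"]
    if element == "S":
        return _CLASS_VOLUMES["S_side"]
    if element == "N":
        return _CLASS_VOLUMES["N_side"]
    if element == "O":
        return _CLASS_VOLUMES["O_side"]
    if element == "C":
        if atom_name in _TERMINAL_METHYLS.get(res_type, ()):
            return _CLASS_VOLUMES["C_methyl"]
        if atom_name in _AROMATIC_RING.get(res_type, ()):
            return _CLASS_VOLUMES["C_aromatic"]
        if atom_name in _POLAR_SP2_CARBON.get(res_type, ()):
            return _CLASS_VOLUMES["C_polar_sp2"]
        if atom_name in _CH_CARBON.get(res_type, ()):
            return _CLASS_VOLUMES["C_CH"]
        return _CLASS_VOLUMES["C_CH2"]
    return FLAT_ATOM_VOLUME


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_ATOMIC_MASS)
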