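"""Bundled per-element and per-residue parameter tables.

Radii are Bondi-style van der Waals radii in Å. Elements missing from the
table fall back to 1.7 Å (generic carbon-like) and the atom is flagged.
"""

from __future__ import annotations

# Bondi vdW radii (Å), upper-cased element symbols.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.63,
    "MN": 1.61,
    "CU": 1.40,
    "NI": 1.63,
}

FALLBACK_VDW_RADIUS = 1.70

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Lennard-Jones well depths (kcal/mol) for the interface-energy proxy,
# loosely following generic force-field magnitudes per element.
LJ_EPSILON: dict[str, float] = {
    "C": 0.10,
    "N": 0.17,
    "O": 0.21,
    "S": 0.25,
    "P": 0.20,
    "H": 0.02,
}
LJ_EPSILON_DEFAULT = 0.10

# Atomic solvation parameters (kcal / (mol Å²)), Eisenberg–McLachlan style:
# positive for apolar atoms (burial favorable), negative for polars.
ASP: dict[str, float] = {
    "C": 0.016,
    "S": 0.021,
    "N": -0.006,
    "O": -0.006,
    "P": -0.006,
    "H": 0.0,
}
ASP_DEFAULT = 0.0

# Hydrogen-bond donor/acceptor heavy atoms per residue (backbone N donor
# except PRO; backbone O acceptor for all).
_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "CYS": (),
}
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "MET": (),
}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def polar_atom_names(resname: str) -> set[str]:
    """Donor/acceptor heavy-atom names for a residue (backbone included)."""
    names = {"O"}
    if resname != "PRO":
        names.add("N")
    names.update(_SIDECHAIN_DONORS.get(resname, ()))
    names.update(_SIDECHAIN_ACCEPTORS.get(resname, ()))
    return names
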