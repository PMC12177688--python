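"""Chemical lookup tables: hydropathy, van der Waals radii, charge schemes.

All distances in Angstrom, charges in units of the elementary charge (e).
"""

from __future__ import annotations

# Kyte-Doolittle hydropathy index per standard residue (dimensionless,
# range -4.5 ... +4.5; positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5,
    "VAL": 4.2,
    "LEU": 3.8,
    "PHE": 2.8,
    "CYS": 2.5,
    "MET": 1.9,
    "ALA": 1.8,
    "GLY": -0.4,
    "THR": -0.7,
    "SER": -0.8,
    "TRP": -0.9,
    "TYR": -1.3,
    "PRO": -1.6,
    "HIS": -3.2,
    "GLU": -3.5,
    "GLN": -3.5,
    "ASP": -3.5,
    "ASN": -3.5,
    "LYS": -3.9,
    "ARG": -4.5,
}

STANDARD_RESIDUES = frozenset(KYTE_DOOLITTLE)

# Per-element van der Waals radii (A) used by the accessible-surface
# calculation; unknown elements fall back to DEFAULT_VDW_RADIUS.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

# Conversion factor: 1 e*A = 4.8032 Debye.
EA_TO_DEBYE = 4.8032

# "formal" charge scheme: integer side-chain charges at pH 7 placed on a
# single representative atom. His neutral; termini ignored.
FORMAL_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "CG"): -1.0,
    ("GLU", "CD"): -1.0,
    ("LYS", "NZ"): +1.0,
    ("ARG", "CZ"): +1.0,
}

# "partial_table" scheme: approximate per-(residue, atom-name) partial
# charges. Backbone values are shared across residues; side-chain values
# cover polar and charged groups. Atoms absent from the table score 0
# (reported via a warning by the dipole routine). The values are a coarse,
# bundled table in the spirit of fixed-charge force fields, adequate for
# ranking pockets by polarity, not for energetics.
_BACKBONE_PARTIAL: dict[str, float] = {
    "N": -0.42,
    "CA": 0.03,
    "C": 0.60,
    "O": -0.57,
}

_SIDECHAIN_PARTIAL: dict[tuple[str, str], float] = {
    ("ASP", "CB"): -0.20, ("ASP", "CG"): 0.75, ("ASP", "OD1"): -0.80, ("ASP", "OD2"): -0.80,
    ("GLU", "CG"): -0.20, ("GLU", "CD"): 0.75, ("GLU", "OE1"): -0.80, ("GLU", "OE2"): -0.80,
    ("LYS", "CE"): 0.25, ("LYS", "NZ"): 0.75,
    ("ARG", "CD"): 0.10, ("ARG", "NE"): -0.55, ("ARG", "CZ"): 0.80,
    ("ARG", "NH1"): -0.10, ("ARG", "NH2"): -0.10, ("ARG", "CB"): 0.0,
    ("HIS", "ND1"): -0.38, ("HIS", "NE2"): -0.57, ("HIS", "CE1"): 0.50,
    ("HIS", "CG"): 0.20, ("HIS", "CD2"): 0.25,
    ("SER", "OG"): -0.66, ("SER", "CB"): 0.21,
    ("THR", "OG1"): -0.68, ("THR", "CB"): 0.27,
    ("TYR", "OH"): -0.56, ("TYR", "CZ"): 0.32,
    ("ASN", "CG"): 0.71, ("ASN", "OD1"): -0.61, ("ASN", "ND2"): -0.92,
    ("GLN", "CD"): 0.71, ("GLN", "OE1"): -0.61, ("GLN", "NE2"): -0.94,
    ("TRP", "NE1"): -0.34, ("TRP", "CE2"): 0.13,
    ("CYS", "SG"): -0.31, ("CYS", "CB"): 0.12,
    ("MET", "SD"): -0.27, ("MET", "CG"): 0.04, ("MET", "CE"): 0.04,
}


def formal_charge(residue_name: str, atom_name: str) -> float | None:
    """Charge under the formal scheme, or None if the atom carries none."""
    return FORMAL_CHARGES.get((residue_name, atom_name))


def partial_charge(residue_name: str, atom_name: str) -> float | None:
    """Charge under the bundled partial-charge table, or None if absent.

    Backbone atoms resolve for every standard residue; side-chain atoms
    only where tabulated.
    """
    if residue_name in STANDARD_RESIDUES and atom_name in _BACKBONE_PARTIAL:
        return _BACKBONE_PARTIAL[atom_name]
    return _SIDECHAIN_PARTIAL.get((residue_name, atom_name))


CHARGE_SCHEMES = {
    "formal": formal_charge,
    "partial_table": partial_charge,
}


def vdw_radius(element: str) -> float:
    """Van der Waals radius for an element symbol (case-insensitive).

    Elements outside the bundled table fall back to the carbon radius.
    """
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)
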