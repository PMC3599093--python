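"""Static chemical reference data: residue codes, heavy-atom names, van der Waals radii."""

from __future__ import annotations

#: Three-letter -> one-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = sorted(ONE_TO_THREE)  # 20 one-letter codes

#: Non-standard residues mapped onto a standard parent (residue name, atom renames).
NONSTANDARD_MAP = {
    "MSE": ("MET", {"SE": "SD"}),
    "SEC": ("CYS", {"SE": "SG"}),
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Canonical heavy atoms per residue (PDB v3 naming). 167 (residue, atom) types total.
RESIDUE_HEAVY_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

#: Side-chain heavy atoms per residue (GLY handled by the CA surrogate rule downstream).
SIDE_CHAIN_HEAVY_ATOMS = {
    res: [a for a in atoms if a not in BACKBONE_ATOMS]
    for res, atoms in RESIDUE_HEAVY_ATOMS.items()
}

#: Bondi-style van der Waals radii (Angstrom), overridable at parse time.
BONDI_RADII = {
    "H": 1.20, "D": 1.20,
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB heavy-atom name (first alphabetic character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"
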