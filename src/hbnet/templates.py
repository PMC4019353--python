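"""Structural templates for the 20 standard amino acids.

Each template lists heavy atoms (PDB v3.3 names), their elements, and bonds
with integer (kekulized) orders.  Aromatic rings are stored in one fixed
Kekule pattern; ring perception downstream treats alternating patterns as
equivalent.  Terminal oxygens (OXT) are attached on demand.
"""

from __future__ import annotations

_BACKBONE_BONDS = [("N", "CA", 1), ("CA", "C", 1), ("C", "O", 2)]

# side-chain atoms (element inferred from the first character of the name,
# two-letter elements never occur in standard residues) and side-chain bonds
_SIDECHAINS: dict[str, tuple[list[str], list[tuple[str, str, int]]]] = {
    "GLY": ([], []),
    "ALA": (["CB"], [("CA", "CB", 1)]),
    "SER": (["CB", "OG"], [("CA", "CB", 1), ("CB", "OG", 1)]),
    "CYS": (["CB", "SG"], [("CA", "CB", 1), ("CB", "SG", 1)]),
    "THR": (["CB", "OG1", "CG2"],
            [("CA", "CB", 1), ("CB", "OG1", 1), ("CB", "CG2", 1)]),
    "VAL": (["CB", "CG1", "CG2"],
            [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1)]),
    "LEU": (["CB", "CG", "CD1", "CD2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 1),
             ("CG", "CD2", 1)]),
    "ILE": (["CB", "CG1", "CG2", "CD1"],
            [("CA", "CB", 1), ("CB", "CG1", 1), ("CB", "CG2", 1),
             ("CG1", "CD1", 1)]),
    "MET": (["CB", "CG", "SD", "CE"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "SD", 1),
             ("SD", "CE", 1)]),
    "PRO": (["CB", "CG", "CD"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
             ("CD", "N", 1)]),
    "PHE": (["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
             ("CD1", "CE1", 1), ("CE1", "CZ", 2), ("CZ", "CE2", 1),
             ("CE2", "CD2", 2), ("CD2", "CG", 1)]),
    "TYR": (["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
             ("CD1", "CE1", 1), ("CE1", "CZ", 2), ("CZ", "CE2", 1),
             ("CE2", "CD2", 2), ("CD2", "CG", 1), ("CZ", "OH", 1)]),
    "TRP": (["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
             "CH2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD1", 2),
             ("CD1", "NE1", 1), ("NE1", "CE2", 1), ("CE2", "CD2", 2),
             ("CD2", "CG", 1), ("CE2", "CZ2", 1), ("CZ2", "CH2", 2),
             ("CH2", "CZ3", 1), ("CZ3", "CE3", 2), ("CE3", "CD2", 1)]),
    "ASP": (["CB", "CG", "OD1", "OD2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2),
             ("CG", "OD2", 1)]),
    "GLU": (["CB", "CG", "CD", "OE1", "OE2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
             ("CD", "OE1", 2), ("CD", "OE2", 1)]),
    "ASN": (["CB", "CG", "OD1", "ND2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "OD1", 2),
             ("CG", "ND2", 1)]),
    "GLN": (["CB", "CG", "CD", "OE1", "NE2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
             ("CD", "OE1", 2), ("CD", "NE2", 1)]),
    "LYS": (["CB", "CG", "CD", "CE", "NZ"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
             ("CD", "CE", 1), ("CE", "NZ", 1)]),
    "ARG": (["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "CD", 1),
             ("CD", "NE", 1), ("NE", "CZ", 1), ("CZ", "NH1", 2),
             ("CZ", "NH2", 1)]),
    # neutral HIS in the N-epsilon-2-H tautomer (the default state)
    "HIS": (["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
            [("CA", "CB", 1), ("CB", "CG", 1), ("CG", "ND1", 1),
             ("ND1", "CE1", 2), ("CE1", "NE2", 1), ("NE2", "CD2", 1),
             ("CD2", "CG", 2)]),
}

STANDARD_RESIDUES = frozenset(_SIDECHAINS)

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def element_of(resname: str, atom_name: str) -> str:
    """Element of a template atom (standard residues use one-letter elements)."""
    return atom_name[0]


def template_for(resname: str) -> dict | None:
    """Atom names, elements and bonds of a standard residue, or None.

    Returns {"atoms": [(name, element), ...], "bonds": [(name_a, name_b,
    order), ...]} including the backbone.  OXT is not included; callers add
    it when present in the records.
    """
    sc = _SIDECHAINS.get(resname)
    if sc is None:
        return None
    names = ["N", "CA", "C", "O"] + sc[0]
    atoms = [(n, element_of(resname, n)) for n in names]
    bonds = list(_BACKBONE_BONDS) + list(sc[1])
    return {"atoms": atoms, "bonds": bonds}
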