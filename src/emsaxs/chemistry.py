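"""Bundled per-atom scattering chemistry for contrast assignment.

For SAXS simulation from an atomic structure each heavy atom carries an
effective electron count Z_eff (its own electrons plus those of its bonded
hydrogens) and an excluded solvent volume V_excl (the volume of displaced
solvent, cubic Angstrom).  The scattering contrast is then
``Z_eff - rho_solvent * V_excl``.

The table below covers the backbone and side-chain heavy atoms of the 20
standard amino acids plus water.  Hydrogen counts follow standard protonation
at neutral pH (Asp/Glu deprotonated, Lys/Arg protonated, neutral His).
Displaced volumes are per atomic group (C, CH, CH2, ..., OH, SH), after the
classic tabulations used by SAXS software.  Entries missing from the table
fall back to bare-element defaults with a warning.
"""

from __future__ import annotations

import warnings

__all__ = ["lookup_atom", "ELEMENT_Z", "GROUP_VOLUMES"]

ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "CO": 27,
    "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

# Displaced solvent volume (A^3) per atomic group, keyed by (element, n_H).
GROUP_VOLUMES = {
    ("C", 0): 16.44,
    ("C", 1): 21.59,
    ("C", 2): 26.74,
    ("C", 3): 31.89,
    ("N", 0): 2.49,
    ("N", 1): 7.64,
    ("N", 2): 12.79,
    ("N", 3): 17.94,
    ("O", 0): 9.13,
    ("O", 1): 14.28,
    ("O", 2): 30.00,   # water molecule
    ("S", 0): 19.86,
    ("S", 1): 25.01,
}

# Bare-element fallback volumes for atoms outside the residue table.
ELEMENT_VOLUMES = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86, "P": 5.73,
    "FE": 7.99, "MG": 16.0, "CA": 31.9, "MN": 9.0, "ZN": 9.3, "CU": 8.8,
    "NA": 4.4, "CL": 24.8, "K": 11.0, "SE": 28.7,
}

# Hydrogens bonded to each backbone heavy atom.
_BACKBONE = {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 0}

# Hydrogens bonded to each side-chain heavy atom, per residue.
_SIDECHAINS: dict[str, dict[str, int]] = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
            "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
    "HOH": {"O": 2},
}


def _hydrogen_count(residue: str, atom_name: str) -> int | None:
    residue = residue.upper()
    atom_name = atom_name.upper()
    table = _SIDECHAINS.get(residue)
    if table is None:
        return None
    if atom_name in table:
        return table[atom_name]
    if residue != "HOH" and atom_name in _BACKBONE:
        n_h = _BACKBONE[atom_name]
        if residue == "PRO" and atom_name == "N":
            return 0  # proline nitrogen carries no amide hydrogen
        if residue == "GLY" and atom_name == "CA":
            return 2
        return n_h
    return None


def lookup_atom(element: str, residue: str, atom_name: str,
                strict: bool = False) -> tuple[float, float]:
    """Return ``(Z_eff, V_excl)`` for a heavy atom.

    ``Z_eff`` is the element's electron count plus one per bonded hydrogen;
    ``V_excl`` is the displaced solvent volume of the atomic group.  Atoms
    outside the bundled table fall back to bare-element values with a warning
    (or raise ``KeyError`` when ``strict``).
    """
    element = element.upper()
    if element not in ELEMENT_Z:
        raise KeyError(f"unknown element {element!r}")
    z = ELEMENT_Z[element]
    n_h = _hydrogen_count(residue, atom_name)
    if n_h is not None:
        volume = GROUP_VOLUMES.get((element, n_h))
        if volume is not None:
            return float(z + n_h), volume
    if strict:
        raise KeyError(f"no table entry for {residue}/{atom_name} ({element})")
    warnings.warn(
        f"atom {residue}/{atom_name}: not in residue table, "
        f"using bare-element values for {element}",
        stacklevel=2,
    )
    return float(z), ELEMENT_VOLUMES.get(element, 16.44)
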