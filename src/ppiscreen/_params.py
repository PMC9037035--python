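"""Atomic parameter tables for the simplified interaction potential.

Radii are Bondi van der Waals radii (Angstrom). Well depths are generic
per-element Lennard-Jones epsilons (kcal/mol) combined by geometric mean.
Partial charges are coarse residue-template values for protein heavy atoms,
with hydrogen charge folded into the bonded heavy atom; atoms not listed
carry zero charge. The potential is a declared open stand-in: it reproduces
the *procedure* of a frozen-coordinate scan, not any commercial package's
absolute energies.
"""

from __future__ import annotations

#: Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Lennard-Jones well depths, kcal/mol, per element.
LJ_EPSILON: dict[str, float] = {
    "H": 0.016,
    "C": 0.086,
    "N": 0.170,
    "O": 0.210,
    "S": 0.250,
    "P": 0.200,
    "F": 0.061,
    "CL": 0.265,
    "BR": 0.320,
    "I": 0.400,
    "SE": 0.290,
}

#: Backbone template charges (all residues), elementary charge units.
BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.35,
    "CA": 0.10,
    "C": 0.55,
    "O": -0.55,
    "OXT": -0.55,
}

#: Side-chain template charges keyed by (residue name, atom name).
SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("ARG", "NE"): -0.10,
    ("ARG", "CZ"): 0.50,
    ("ARG", "NH1"): 0.30,
    ("ARG", "NH2"): 0.30,
    ("LYS", "NZ"): 0.80,
    ("ASP", "CG"): 0.30,
    ("ASP", "OD1"): -0.65,
    ("ASP", "OD2"): -0.65,
    ("GLU", "CD"): 0.30,
    ("GLU", "OE1"): -0.65,
    ("GLU", "OE2"): -0.65,
    ("SER", "OG"): -0.35,
    ("THR", "OG1"): -0.35,
    ("TYR", "OH"): -0.35,
    ("CYS", "SG"): -0.20,
    ("MET", "SD"): -0.10,
    ("ASN", "CG"): 0.45,
    ("ASN", "OD1"): -0.55,
    ("ASN", "ND2"): -0.25,
    ("GLN", "CD"): 0.45,
    ("GLN", "OE1"): -0.55,
    ("GLN", "NE2"): -0.25,
    ("HIS", "ND1"): -0.35,
    ("HIS", "NE2"): -0.35,
    ("TRP", "NE1"): -0.20,
}

#: Coulomb conversion constant, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Residue names treated as water and discarded on parsing.
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Atom names retained when a side chain is truncated to alanine.
ALANINE_KEPT_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "CB",
     "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HB1", "HB2", "HB3"}
)


def partial_charge(residue_name: str, atom_name: str) -> float:
    """Template partial charge for a named protein atom (0 if unlisted)."""
    if atom_name in BACKBONE_CHARGES:
        return BACKBONE_CHARGES[atom_name]
    return SIDECHAIN_CHARGES.get((residue_name, atom_name), 0.0)
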