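"""Two-partner complexes, interface detection, and frozen virtual alanine scanning.

The scan follows the frozen-coordinate convention: a receptor residue is
virtually mutated to alanine by deleting its side-chain atoms beyond the
C-beta, with every remaining atom kept exactly in place — no minimization,
no rebuilding, no rotation about the C-alpha/C-beta bond.  The loss of
binding affinity ("delta affinity", kcal/mol) attributed to the residue is
then exactly the summed pairwise attraction between the deleted atoms and
the partner side.  Glycine and alanine have nothing to delete and report 0
by convention.  Interface residues whose delta affinity reaches a threshold
(default 4 kcal/mol) are called hot spots.

The pairwise potential is a declared simplified stand-in: Lennard-Jones 6-12
on Bondi radii with geometric-mean well depths, plus Coulomb with a
distance-dependent dielectric eps(r) = 4r and residue-template charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._params import (
    ALANINE_KEPT_ATOMS,
    COULOMB_CONSTANT,
    LJ_EPSILON,
    VDW_RADII,
    WATER_RESIDUES,
    partial_charge,
)
from .errors import ConfigurationError, PDBFormatError, ResidueNotFoundError

#: (chain_id, residue_number, residue_name)
ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """One atom of a complex, with assigned radius and template charge."""

    id: int
    name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_number: int
    chain_id: str
    vdw_radius: float
    partial_charge: float

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.residue_name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Complex:
    """Atoms of a two-partner structure split into receptor and partner chains."""

    atoms: list[Atom]
    receptor_chains: frozenset[str]
    partner_chains: frozenset[str]

    def __post_init__(self) -> None:
        self.receptor_chains = frozenset(self.receptor_chains)
        self.partner_chains = frozenset(self.partner_chains)
        if not self.receptor_chains or not self.partner_chains:
            raise ConfigurationError("receptor and partner chain sets must be non-empty")
        overlap = self.receptor_chains & self.partner_chains
        if overlap:
            raise ConfigurationError(f"chains on both sides: {sorted(overlap)}")
        for a in self.atoms:
            if a.chain_id not in self.receptor_chains | self.partner_chains:
                raise ConfigurationError(f"atom {a.id} on unassigned chain {a.chain_id!r}")

    def receptor_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id in self.receptor_chains]

    def partner_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id in self.partner_chains]

    def residue_atoms(self, residue: ResidueId) -> list[Atom]:
        chain, number, name = residue
        return [
            a
            for a in self.atoms
            if a.chain_id == chain and a.residue_number == number and a.residue_name == name
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Complex":
        """Rigidly transformed copy (rotation 3x3, translation 3-vector)."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        atoms = [
            replace(a, coords=tuple(rot @ np.asarray(a.coords) + tr)) for a in self.atoms
        ]
        return Complex(atoms, self.receptor_chains, self.partner_chains)


@dataclass(frozen=True)
class ResidueScanResult:
    """Per-residue outcome of the virtual alanine scan."""

    residue: ResidueId
    delta_affinity: float  # kcal/mol; >= 0 for attractive side chains
    is_hot_spot: bool


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the simplified pairwise potential and hot-spot call.

    interaction_cutoff limits which atom pairs contribute (Angstrom);
    hot_spot_threshold is the delta-affinity level (kcal/mol) at or above
    which a residue is called a hot spot.
    """

    interaction_cutoff: float = 6.0
    hot_spot_threshold: float = 4.0
    lj_epsilon: dict = field(default_factory=lambda: dict(LJ_EPSILON))
    dielectric_slope: float = 4.0  # eps(r) = dielectric_slope * r

    def __post_init__(self) -> None:
        if self.interaction_cutoff <= 0:
            raise ConfigurationError("interaction_cutoff must be positive")
        if self.hot_spot_threshold <= 0:
            raise ConfigurationError("hot_spot_threshold must be positive")


def _make_atom(idx: int, name: str, element: str, pos, res_name: str,
               res_num: int, chain: str) -> Atom:
    el = element.upper()
    if el not in VDW_RADII:
        raise PDBFormatError(f"unknown element {element!r} for atom {name} "
                             f"in {res_name} {chain}{res_num}")
    return Atom(
        id=idx,
        name=name,
        element=el,
        coords=(float(pos[0]), float(pos[1]), float(pos[2])),
        residue_name=res_name,
        residue_number=res_num,
        chain_id=chain,
        vdw_radius=VDW_RADII[el],
        partial_charge=partial_charge(res_name, name),
    )


def parse_complex(pdb_text: str, receptor_chains, partner_chains) -> Complex:
    """Parse PDB text into a two-partner :class:`Complex`.

    Reads ATOM/HETATM records of MODEL 1 only, keeps only the named chains,
    discards waters, and assigns Bondi radii and template charges.  Raises
    :class:`PDBFormatError` for malformed records or unrecognized elements
    and :class:`ConfigurationError` when a requested chain is absent.
    """
    receptor_chains = frozenset(receptor_chains)
    partner_chains = frozenset(partner_chains)
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the bad line
        raise PDBFormatError(f"cannot parse PDB text: {exc}") from exc
    if len(structure) == 0:
        raise PDBFormatError("PDB text contains no coordinate model")
    model = structure[0]

    wanted = receptor_chains | partner_chains
    present = {chain.name for chain in model}
    missing = wanted - present
    if missing:
        raise ConfigurationError(
            f"chain(s) {sorted(missing)} not present in structure (found {sorted(present)})"
        )

    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        if chain.name not in wanted:
            continue
        for residue in chain:
            if residue.name.strip() in WATER_RESIDUES:
                continue
            for at in residue:
                element = at.element.name if at.element.name else at.name[:1]
                atoms.append(
                    _make_atom(idx, at.name, element, at.pos,
                               residue.name.strip(), residue.seqid.num, chain.name)
                )
                idx += 1
    return Complex(atoms, receptor_chains, partner_chains)


def interface_residues(complex_: Complex, cutoff: float = 4.5) -> list[ResidueId]:
    """Receptor residues with a heavy atom within ``cutoff`` of any partner heavy atom.

    Sorted by (chain, residue number).  A local geometric criterion stands in
    for interface lists curated by external structure databases.
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    rec = [a for a in complex_.receptor_atoms() if a.is_heavy]
    par = [a for a in complex_.partner_atoms() if a.is_heavy]
    if not rec or not par:
        return []
    tree = cKDTree(np.array([a.coords for a in par]))
    hits = tree.query_ball_point(np.array([a.coords for a in rec]), r=cutoff)
    found = {rec[i].residue_id for i, neigh in enumerate(hits) if neigh}
    return sorted(found, key=lambda r: (r[0], r[1]))


def pair_affinity(a: Atom, b: Atom, params: EnergyParams) -> float:
    """Attraction between two atoms in kcal/mol (positive = favorable).

    Negated sum of a 6-12 Lennard-Jones term (minimum at the radius sum) and
    a Coulomb term with distance-dependent dielectric eps(r) = slope * r.
    """
    dx = a.coords[0] - b.coords[0]
    dy = a.coords[1] - b.coords[1]
    dz = a.coords[2] - b.coords[2]
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    if r > params.interaction_cutoff or r == 0.0:
        return 0.0
    rmin = a.vdw_radius + b.vdw_radius
    eps = math.sqrt(
        params.lj_epsilon.get(a.element, 0.1) * params.lj_epsilon.get(b.element, 0.1)
    )
    s6 = (rmin / r) ** 6
    lj = eps * (s6 * s6 - 2.0 * s6)
    coul = COULOMB_CONSTANT * a.partial_charge * b.partial_charge / (
        params.dielectric_slope * r * r
    )
    return -(lj + coul)


def binding_affinity(receptor_atoms: list[Atom], partner_atoms: list[Atom],
                     params: EnergyParams) -> float:
    """Total cross-side pairwise attraction within the interaction cutoff."""
    if not receptor_atoms or not partner_atoms:
        return 0.0
    tree = cKDTree(np.array([a.coords for a in partner_atoms]))
    pairs = tree.query_ball_point(
        np.array([a.coords for a in receptor_atoms]), r=params.interaction_cutoff
    )
    total = 0.0
    for i, neigh in enumerate(pairs):
        for j in neigh:
            total += pair_affinity(receptor_atoms[i], partner_atoms[j], params)
    return total


def alanine_scan(complex_: Complex, residue: ResidueId,
                 params: EnergyParams | None = None) -> ResidueScanResult:
    """Delta affinity of virtually mutating one receptor residue to alanine.

    Both states share identical frozen coordinates, so the difference reduces
    to the pairwise attraction between the truncated atoms (everything beyond
    C-beta) and the partner side.  GLY and ALA return 0 by convention.
    """
    params = params or EnergyParams()
    chain, number, name = residue
    if chain not in complex_.receptor_chains:
        raise ConfigurationError(f"residue {residue} is not on the receptor side")
    res_atoms = complex_.residue_atoms(residue)
    if not res_atoms:
        raise ResidueNotFoundError(f"residue {residue} not found in complex")

    if name in ("GLY", "ALA"):
        delta = 0.0
    else:
        removed = [a for a in res_atoms if a.name not in ALANINE_KEPT_ATOMS]
        delta = binding_affinity(removed, complex_.partner_atoms(), params)
    return ResidueScanResult(
        residue=residue,
        delta_affinity=delta,
        is_hot_spot=delta >= params.hot_spot_threshold,
    )


def scan_interface(complex_: Complex, params: EnergyParams | None = None,
                   interface_cutoff: float = 4.5) -> list[ResidueScanResult]:
    """Alanine-scan every interface residue of the receptor side."""
    params = params or EnergyParams()
    return [
        alanine_scan(complex_, res, params)
        for res in interface_residues(complex_, interface_cutoff)
    ]


def call_hot_spots(scan: list[ResidueScanResult], threshold: float = 4.0) -> list[ResidueId]:
    """Residues whose delta affinity meets the threshold, sorted by (chain, number)."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    hits = [r.residue for r in scan if r.delta_affinity >= threshold]
    return sorted(hits, key=lambda r: (r[0], r[1]))
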