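"""Per-pose interaction profiling: H-bonds, attractive VDW contacts, buried surface.

A docked pose is summarized by the three properties used for triage:

* geometric hydrogen bonds between receptor and ligand polar atoms,
* the count of *attractive* van der Waals contacts — heavy-atom pairs whose
  separation, relative to the sum of their van der Waals radii, falls inside
  a "good contact" window (clashes and distant pairs are excluded),
* the buried surface area (BSA, squared Angstrom): solvent-accessible surface
  lost on complex formation, summed over both partners.

SASA uses the Shrake-Rupley sphere-point method with a deterministic
golden-spiral lattice, so every number is bit-reproducible.  The docking
score is an external quantity and is only carried through.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .structures import Atom, ResidueId

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
_MAX_H_BOND_LENGTH = 1.3  # Angstrom; H considered covalently bonded to a polar atom


@dataclass(frozen=True)
class GeometryParams:
    """Geometric criteria for interaction profiling.

    hbond_distance_cutoff: donor-acceptor heavy-atom distance, Angstrom.
    hbond_angle_cutoff: D-H...A angle, degrees, applied only when explicit
        hydrogens are present.
    vdw_ratio_window: allowed d/(r_i+r_j) interval for an attractive contact.
    sasa_probe_radius / sasa_points: solvent probe (Angstrom) and lattice size.
    """

    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0
    vdw_ratio_window: tuple[float, float] = (0.89, 1.30)
    sasa_probe_radius: float = 1.4
    sasa_points: int = 960

    def __post_init__(self) -> None:
        lo, hi = self.vdw_ratio_window
        if not (0 < lo < hi):
            raise ConfigurationError("vdw_ratio_window must satisfy 0 < lower < upper")
        if min(self.hbond_distance_cutoff, self.hbond_angle_cutoff,
               self.sasa_probe_radius, self.sasa_points) <= 0:
            raise ConfigurationError("all geometry parameters must be positive")


@dataclass(frozen=True)
class HBond:
    donor_atom: Atom
    acceptor_atom: Atom
    receptor_residue: ResidueId
    distance: float
    angle: float | None  # degrees; None when no explicit hydrogens


@dataclass
class PoseProfile:
    """Interaction summary of one docked pose."""

    molecule_id: str
    hbond_residues: set[ResidueId]
    vdw_contact_count: int
    vdw_residues: set[ResidueId]
    bsa: float
    docking_score: float | None = None
    hbonds: list[HBond] = field(default_factory=list)


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def _local_frames(coords: np.ndarray) -> np.ndarray:
    """Per-atom orthonormal frames built from nearest-neighbor directions.

    Anchoring each atom's point lattice to its local geometry makes the
    surface areas rotate with the molecule, so rigid motions leave SASA and
    BSA unchanged up to floating-point error rather than lattice error.
    """
    n = len(coords)
    frames = np.tile(np.eye(3), (n, 1, 1))
    if n < 2:
        return frames
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=min(3, n))
    for i in range(n):
        e1 = coords[idx[i, 1]] - coords[i]
        norm = np.linalg.norm(e1)
        if norm == 0:
            continue
        e1 = e1 / norm
        v = (coords[idx[i, 2]] - coords[i]) if idx.shape[1] > 2 \
            else np.array([0.0, 0.0, 1.0])
        e2 = v - np.dot(v, e1) * e1
        n2 = np.linalg.norm(e2)
        if n2 < 1e-8:  # collinear neighbors: any fixed perpendicular
            v = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 \
                else np.array([0.0, 1.0, 0.0])
            e2 = v - np.dot(v, e1) * e1
            n2 = np.linalg.norm(e2)
        e2 = e2 / n2
        frames[i] = np.column_stack([e1, e2, np.cross(e1, e2)])
    return frames


def sasa(atoms: list[Atom], params: GeometryParams | None = None) -> float:
    """Shrake-Rupley solvent-accessible surface area of heavy atoms, A^2."""
    params = params or GeometryParams()
    heavy = [a for a in atoms if a.is_heavy]
    if not heavy:
        return 0.0
    coords = np.array([a.coords for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy]) + params.sasa_probe_radius
    sphere = _unit_sphere_points(params.sasa_points)
    frames = _local_frames(coords)
    tree = cKDTree(coords)
    max_r = radii.max()
    area = 0.0
    for i in range(len(heavy)):
        pts = coords[i] + radii[i] * (sphere @ frames[i].T)
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        area += accessible.mean() * 4.0 * math.pi * radii[i] ** 2
    return area


def buried_surface_area(receptor: list[Atom], ligand: list[Atom],
                        params: GeometryParams | None = None) -> float:
    """BSA = SASA(receptor) + SASA(ligand) - SASA(complex), clamped at 0.

    Two-sided convention: the buried area of both partners is summed.
    """
    params = params or GeometryParams()
    free = sasa(receptor, params) + sasa(ligand, params)
    bound = sasa(list(receptor) + list(ligand), params)
    return max(0.0, free - bound)


def _attached_hydrogens(polar: list[Atom], all_atoms: list[Atom]) -> dict[int, list[Atom]]:
    """Hydrogens covalently bonded (within 1.3 A) to each polar atom, by atom id."""
    hydrogens = [a for a in all_atoms if a.element == "H"]
    out: dict[int, list[Atom]] = {a.id: [] for a in polar}
    if not hydrogens:
        return out
    hcoords = np.array([h.coords for h in hydrogens])
    tree = cKDTree(hcoords)
    for a in polar:
        for j in tree.query_ball_point(a.coords, _MAX_H_BOND_LENGTH):
            out[a.id].append(hydrogens[j])
    return out


def _angle_deg(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a) - np.asarray(b)
    v2 = np.asarray(c) - np.asarray(b)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def detect_hbonds(receptor: list[Atom], ligand: list[Atom],
                  params: GeometryParams | None = None) -> list[HBond]:
    """Geometric hydrogen bonds between receptor and ligand polar atoms.

    A candidate pair is any receptor N/O/S with any ligand N/O/S at
    donor-acceptor distance <= cutoff.  When either atom carries explicit
    hydrogens the best D-H...A angle must reach the angle cutoff; structures
    without hydrogens are judged on distance alone.  With no hydrogen the
    receptor atom is recorded as the donor by convention.
    """
    params = params or GeometryParams()
    if not ligand:
        raise ConfigurationError("ligand atom set is empty")
    rec_polar = [a for a in receptor if a.element in POLAR_ELEMENTS]
    lig_polar = [a for a in ligand if a.element in POLAR_ELEMENTS]
    if not rec_polar or not lig_polar:
        return []
    rec_h = _attached_hydrogens(rec_polar, receptor)
    lig_h = _attached_hydrogens(lig_polar, ligand)

    tree = cKDTree(np.array([a.coords for a in lig_polar]))
    hits = tree.query_ball_point(
        np.array([a.coords for a in rec_polar]), params.hbond_distance_cutoff
    )
    bonds: list[HBond] = []
    for i, neigh in enumerate(hits):
        ra = rec_polar[i]
        for j in sorted(neigh):
            la = lig_polar[j]
            dist = float(np.linalg.norm(np.asarray(ra.coords) - np.asarray(la.coords)))
            candidates = [(ra, h, la) for h in rec_h[ra.id]] + \
                         [(la, h, ra) for h in lig_h[la.id]]
            if candidates:
                best = max(
                    candidates,
                    key=lambda dha: _angle_deg(dha[0].coords, dha[1].coords, dha[2].coords),
                )
                angle = _angle_deg(best[0].coords, best[1].coords, best[2].coords)
                if angle < params.hbond_angle_cutoff:
                    continue
                donor, acceptor = best[0], best[2]
            else:
                angle = None
                donor, acceptor = ra, la
            bonds.append(HBond(donor, acceptor, ra.residue_id, dist, angle))
    return bonds


def count_attractive_vdw(receptor: list[Atom], ligand: list[Atom],
                         params: GeometryParams | None = None
                         ) -> tuple[int, dict[ResidueId, int]]:
    """Count heavy-atom pairs at favorable van der Waals separation.

    A pair counts when d/(r_i + r_j) lies inside the ratio window; the
    per-residue map partitions the count by receptor residue.
    """
    params = params or GeometryParams()
    lo, hi = params.vdw_ratio_window
    rec = [a for a in receptor if a.is_heavy]
    lig = [a for a in ligand if a.is_heavy]
    per_residue: dict[ResidueId, int] = {}
    if not rec or not lig:
        return 0, per_residue
    lig_coords = np.array([a.coords for a in lig])
    tree = cKDTree(lig_coords)
    max_sum = max(a.vdw_radius for a in rec) + max(a.vdw_radius for a in lig)
    total = 0
    for i, ra in enumerate(rec):
        for j in tree.query_ball_point(ra.coords, hi * max_sum):
            la = lig[j]
            d = float(np.linalg.norm(np.asarray(ra.coords) - lig_coords[j]))
            ratio = d / (ra.vdw_radius + la.vdw_radius)
            if lo <= ratio <= hi:
                total += 1
                per_residue[ra.residue_id] = per_residue.get(ra.residue_id, 0) + 1
    return total, per_residue


def profile_pose(receptor: list[Atom], ligand: list[Atom],
                 params: GeometryParams | None = None,
                 docking_score: float | None = None,
                 molecule_id: str = "") -> PoseProfile:
    """Assemble the full interaction profile of one pose."""
    params = params or GeometryParams()
    if not ligand:
        raise ConfigurationError("ligand atom set is empty")
    bonds = detect_hbonds(receptor, ligand, params)
    count, by_residue = count_attractive_vdw(receptor, ligand, params)
    return PoseProfile(
        molecule_id=molecule_id,
        hbond_residues={b.receptor_residue for b in bonds},
        vdw_contact_count=count,
        vdw_residues=set(by_residue),
        bsa=buried_surface_area(receptor, ligand, params),
        docking_score=docking_score,
        hbonds=bonds,
    )
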