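"""Synthetic inputs with machine-readable ground truth.

Three generators cover the pipeline's input surface:

* :func:`make_toy_complex` — a two-chain complex whose receptor residues are
  widely spaced rigid clusters; chosen residues get a ligand polar atom
  planted at hydrogen-bond distance and/or ligand carbons planted inside the
  attractive van der Waals window, so the interaction profiler provably
  recovers the planted counts.
* :func:`make_pose_table` — docked-pose records drawn inside the Best
  region, the Worst region, or the gap between them, with exact labels.
* :func:`make_learning_set` — a labeled descriptor matrix: standard-normal
  noise, with the Best class shifted by a stated effect size (in pooled
  standard deviations) on a stated subset of informative descriptors.

Each generator returns its output together with a truth ledger (a plain
dict) that downstream recovery tests assert against.  Geometry here is
deliberately unphysical — isolated atom clusters, not real protein
conformations — because its only job is to exercise the detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._params import VDW_RADII, partial_charge
from .criteria import BEST, NEITHER, WORST, LabelThresholds, PoseRecord
from .descriptors import DescriptorTable
from .errors import ConfigurationError
from .structures import Atom, Complex

# planted geometry constants (Angstrom)
_HBOND_DISTANCE = 2.6  # inside the 3.5 H-bond cutoff, below the VDW ratio window
_CC_CONTACT = VDW_RADII["C"] * 2.0  # mid-window carbon-carbon contact, ratio 1.0
_RESIDUE_SPACING = 25.0


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a toy two-chain complex with planted interactions."""

    n_receptor_residues: int = 6
    planted_hbond_residues: frozenset[int] = frozenset()  # residue numbers, 1-based
    planted_contact_counts: dict[int, int] = field(default_factory=dict)
    ligand_atom_count: int = 0  # extra far-away ligand atoms beyond planted ones
    seed: int = 0

    def __post_init__(self) -> None:
        planted = set(self.planted_hbond_residues) | set(self.planted_contact_counts)
        bad = [r for r in planted if not 1 <= r <= self.n_receptor_residues]
        if bad:
            raise ConfigurationError(f"planted residues outside range: {sorted(bad)}")
        if any(c < 1 for c in self.planted_contact_counts.values()):
            raise ConfigurationError("planted contact counts must be >= 1")
        if max(self.planted_contact_counts.values(), default=0) > 8:
            raise ConfigurationError("at most 8 contacts fit one residue apex")


@dataclass(frozen=True)
class LearningSetSpec:
    """Recipe for a labeled descriptor matrix with a planted class shift."""

    n_best: int = 68
    n_worst: int = 69
    n_descriptors: int = 50
    n_informative: int = 3
    effect_size: float = 2.0  # pooled standard deviations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ConfigurationError("n_informative cannot exceed n_descriptors")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if min(self.n_best, self.n_worst) < 1:
            raise ConfigurationError("both classes need at least one molecule")


def _atom(idx, name, element, coords, resname, resnum, chain) -> Atom:
    return Atom(
        id=idx, name=name, element=element, coords=tuple(float(c) for c in coords),
        residue_name=resname, residue_number=resnum, chain_id=chain,
        vdw_radius=VDW_RADII[element],
        partial_charge=partial_charge(resname, name),
    )


def make_toy_complex(spec: ComplexSpec) -> tuple[Complex, dict]:
    """Build the toy complex and its truth ledger.

    Receptor residues (chain A, SER for H-bond donors/acceptors at the
    backbone O, LEU otherwise) sit on a line 25 A apart.  For each planted
    H-bond a ligand nitrogen is placed 2.6 A below the residue's backbone O;
    planted contacts are ligand carbons fanned 3.4 A above the C-beta.
    Extra ligand atoms are placed ~60 A away from every receptor atom.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    idx = 0
    truth_hb = sorted(spec.planted_hbond_residues)
    truth_vdw = dict(sorted(spec.planted_contact_counts.items()))

    lig_coords: list[tuple[str, str, np.ndarray]] = []  # (name, element, xyz)
    for resnum in range(1, spec.n_receptor_residues + 1):
        cx = resnum * _RESIDUE_SPACING
        resname = "SER" if resnum in spec.planted_hbond_residues else "LEU"
        center = np.array([cx, 0.0, 0.0])
        # compact rigid cluster: backbone in the z=0 plane, O below, CB above
        cluster = {
            "N": center + (1.4, 0.2, 0.0),
            "CA": center + (0.0, 0.0, 0.0),
            "C": center + (-1.3, 0.6, 0.0),
            "O": center + (0.1, -0.2, -2.2),
            "CB": center + (0.0, 0.1, 1.5),
        }
        for name, xyz in cluster.items():
            atoms.append(_atom(idx, name, name[0], xyz, resname, resnum, "A"))
            idx += 1
        if resnum in spec.planted_hbond_residues:
            pos = cluster["O"] + (0.0, 0.0, -_HBOND_DISTANCE)
            lig_coords.append((f"N{resnum}", "N", pos))
        for c in range(spec.planted_contact_counts.get(resnum, 0)):
            # fan of directions within 25 degrees of +z: stays in the ratio
            # window w.r.t. CB, outside it w.r.t. every other cluster atom
            theta = 0.0 if c == 0 else math.radians(25.0)
            phi = 2.0 * math.pi * (c - 1) / 7.0
            direction = np.array([
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta),
            ])
            pos = cluster["CB"] + _CC_CONTACT * direction
            lig_coords.append((f"C{resnum}_{c}", "C", pos))

    for e in range(spec.ligand_atom_count):
        pos = np.array([-60.0 - 5.0 * e, 40.0, 40.0]) + rng.normal(0, 0.5, 3)
        lig_coords.append((f"CX{e}", "C", pos))

    if not lig_coords:
        raise ConfigurationError("spec plants no ligand atoms at all")
    for name, element, xyz in lig_coords:
        atoms.append(_atom(idx, name, element, xyz, "LIG", 1, "B"))
        idx += 1

    complex_ = Complex(atoms, frozenset({"A"}), frozenset({"B"}))
    ledger = {
        "hbond_residues": [("A", r, "SER") for r in truth_hb],
        "vdw_contact_counts": {
            ("A", r, "SER" if r in spec.planted_hbond_residues else "LEU"): c
            for r, c in truth_vdw.items()
        },
        "total_vdw_contacts": sum(truth_vdw.values()),
        "interface_residues": sorted(set(truth_hb) | set(truth_vdw)),
        "seed": spec.seed,
    }
    return complex_, ledger


def complex_to_pdb(complex_: Complex) -> str:
    """Serialize a complex as minimal PDB text (round-trips via parse_complex)."""
    lines = []
    for i, a in enumerate(complex_.atoms, 1):
        x, y, z = a.coords
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4.4s} {a.residue_name:<3s} {a.chain_id}"
            f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_pose_table(n: int, best_fraction: float, worst_fraction: float,
                    thresholds: LabelThresholds = LabelThresholds(),
                    seed: int = 0) -> tuple[list[PoseRecord], list[str]]:
    """Draw pose records inside the Best region, Worst region, or the gap.

    Returns the records and their ground-truth labels; applying the same
    thresholds recovers the labels exactly.
    """
    if best_fraction < 0 or worst_fraction < 0 or best_fraction + worst_fraction > 1:
        raise ConfigurationError("fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    n_best = round(n * best_fraction)
    n_worst = round(n * worst_fraction)
    n_mid = n - n_best - n_worst
    records, labels = [], []
    t = thresholds

    def draw(kind: str, i: int) -> PoseRecord:
        if kind == BEST:
            score = t.best_score_below - rng.uniform(0.2, 4.0)
            bsa = t.best_bsa_min + rng.uniform(0, 300)
            vdw = int(t.best_vdw_min + rng.integers(0, 250))
        elif kind == WORST:
            score = t.worst_score_min + rng.uniform(0, 1.0)
            bsa = t.worst_bsa_max - rng.uniform(0, 300)
            vdw = int(rng.integers(10, t.worst_vdw_max + 1))
        else:  # strictly between the two regions on every property
            score = rng.uniform(t.best_score_below, t.worst_score_min - 0.1)
            bsa = rng.uniform(t.worst_bsa_max + 1, t.best_bsa_min - 1)
            vdw = int(rng.integers(t.worst_vdw_max + 1, t.best_vdw_min))
        return PoseRecord(f"SYN{i:05d}", round(float(score), 2), vdw, round(float(bsa), 1))

    i = 0
    for kind, count in ((BEST, n_best), (WORST, n_worst), (NEITHER, n_mid)):
        for _ in range(count):
            records.append(draw(kind, i))
            labels.append(kind)
            i += 1
    order = rng.permutation(n)
    return [records[j] for j in order], [labels[j] for j in order]


def make_learning_set(spec: LearningSetSpec) -> tuple[DescriptorTable, list[str]]:
    """Labeled descriptor table with a planted Best-vs-Worst separation.

    Worst rows are standard normal per descriptor; Best rows add
    ``effect_size`` (pooled SDs, since the noise SD is 1) on the informative
    descriptors only.  Returns the table and the informative descriptor names.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_best + spec.n_worst
    names = [f"D{j:03d}" for j in range(spec.n_descriptors)]
    informative = sorted(rng.choice(spec.n_descriptors, size=spec.n_informative,
                                    replace=False).tolist())
    X = rng.standard_normal((n, spec.n_descriptors))
    X[: spec.n_best, informative] += spec.effect_size
    ids = [f"M{i:05d}" for i in range(n)]
    labels = pd.Series([BEST] * spec.n_best + [WORST] * spec.n_worst,
                       index=ids, name="label")
    frame = pd.DataFrame(X, index=ids, columns=names)
    order = rng.permutation(n)
    frame = frame.iloc[order]
    labels = labels.iloc[order]
    table = DescriptorTable(values=frame, labels=labels)
    return table, [names[j] for j in informative]
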