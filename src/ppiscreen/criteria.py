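"""Pose-filter criteria, Best/Worst labeling, and three-property ranking.

Docked poses are triaged in two ways.  Geometric criteria demand specific
interactions with the receptor's hot-spot residues (an H-bond to ARG87 and
attractive VDW contact with a named residue set; sub-site variants cover
each half of the binding site).  Independently, poses are labeled "Best"
or "Worst" by thresholds on the three ranking properties — docking score,
attractive VDW contact count, and buried surface area — to form the two
classes of the ligand-based learning set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import rankdata

from .errors import ConfigurationError
from .pose import PoseProfile

BEST = "Best"
WORST = "Worst"
NEITHER = "neither"


def _resnames(profile_residues) -> set[str]:
    """Residue names like 'ARG87' from (chain, number, name) ids or strings."""
    out = set()
    for r in profile_residues:
        if isinstance(r, str):
            out.add(r)
        else:
            out.add(f"{r[2]}{r[1]}")
    return out


@dataclass(frozen=True)
class CriteriaSet:
    """Named set of required interactions with receptor residues."""

    name: str
    required_hbond_residues: frozenset[str]
    required_vdw_residues: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.required_hbond_residues | self.required_vdw_residues):
            raise ConfigurationError("criteria set requires at least one residue")


@dataclass(frozen=True)
class PoseRecord:
    """One row of a docked-pose table: id, docking score, VDW count, BSA."""

    molecule_id: str
    docking_score: float
    vdw_contacts: int
    bsa: float

    def __post_init__(self) -> None:
        if self.vdw_contacts < 0 or self.bsa < 0:
            raise ConfigurationError("vdw_contacts and bsa must be non-negative")


@dataclass(frozen=True)
class LabelThresholds:
    """Best/Worst regions in (docking score, BSA, VDW count) space.

    Best requires docking_score strictly below ``best_score_below`` together
    with BSA and VDW at or above their floors; Worst requires docking_score
    at or above ``worst_score_min`` with BSA and VDW at or below their caps.
    The two regions are disjoint by construction.
    """

    best_score_below: float = -3.0
    best_bsa_min: float = 750.0
    best_vdw_min: int = 250
    worst_score_min: float = -1.0
    worst_bsa_max: float = 600.0
    worst_vdw_max: int = 150

    def __post_init__(self) -> None:
        if not (self.best_score_below <= self.worst_score_min
                and self.best_bsa_min > self.worst_bsa_max
                and self.best_vdw_min > self.worst_vdw_max):
            raise ConfigurationError("Best and Worst regions must be disjoint")


#: Geometric criteria spanning the full docking site: H-bond to ARG87 plus
#: attractive VDW contact with the remaining hot spots.
FULL_SITE = CriteriaSet(
    "full_site",
    frozenset({"ARG87"}),
    frozenset({"TYR44", "GLU45", "MET83", "LEU81", "TYR147"}),
)

#: Sub-site A: the MET83/LEU81/TYR147 half of the site.
SUBSITE_A = CriteriaSet(
    "subsite_a",
    frozenset({"ARG87"}),
    frozenset({"MET83", "LEU81", "TYR147"}),
)

#: Sub-site B: the TYR44/GLU45 half, close enough to include TRP62.
SUBSITE_B = CriteriaSet(
    "subsite_b",
    frozenset({"ARG87"}),
    frozenset({"TYR44", "GLU45", "TRP62"}),
)

CRITERIA_PRESETS: dict[str, CriteriaSet] = {
    c.name: c for c in (FULL_SITE, SUBSITE_A, SUBSITE_B)
}

#: Default Best/Worst thresholds used to build the learning classes.
BEST_WORST_THRESHOLDS = LabelThresholds()

#: Docked-pose records of the ten candidate molecules selected for in vitro
#: testing (docking score kcal/mol, attractive VDW contacts, BSA A^2).
REFERENCE_POSES: tuple[PoseRecord, ...] = (
    PoseRecord("Z49720304", -4.0, 292, 843.0),
    PoseRecord("Z18823321", -3.8, 233, 883.0),
    PoseRecord("Z1290281203", -3.4, 272, 848.0),
    PoseRecord("Z1033235866", -3.4, 220, 751.0),
    PoseRecord("Z131775002", -4.4, 211, 748.0),
    PoseRecord("Z56788505", -5.4, 316, 1039.0),
    PoseRecord("Z786028994", -4.3, 241, 832.0),
    PoseRecord("Z1172207733", -2.4, 293, 986.0),
    PoseRecord("Z49734016", -7.0, 453, 779.0),
    PoseRecord("Z66693270", -3.3, 210, 818.0),
)


def passes_criteria(profile: PoseProfile, criteria: CriteriaSet) -> bool:
    """True iff the profile satisfies every required interaction."""
    hb = _resnames(profile.hbond_residues)
    vdw = _resnames(profile.vdw_residues)
    return (criteria.required_hbond_residues <= hb
            and criteria.required_vdw_residues <= vdw)


def label_best_worst(record: PoseRecord,
                     thresholds: LabelThresholds = BEST_WORST_THRESHOLDS) -> str:
    """Label a pose record Best, Worst, or neither."""
    if (record.docking_score < thresholds.best_score_below
            and record.bsa >= thresholds.best_bsa_min
            and record.vdw_contacts >= thresholds.best_vdw_min):
        return BEST
    if (record.docking_score >= thresholds.worst_score_min
            and record.bsa <= thresholds.worst_bsa_max
            and record.vdw_contacts <= thresholds.worst_vdw_max):
        return WORST
    return NEITHER


def rank_molecules(records: list[PoseRecord]) -> list[PoseRecord]:
    """Order records by the summed ranks of the three properties.

    Each record receives rank(docking score, ascending) + rank(VDW contacts,
    descending) + rank(BSA, descending); lower sums rank higher.  Ties break
    by docking score, then molecule id, so the order is deterministic and
    permutation-invariant.
    """
    if not records:
        raise ConfigurationError("cannot rank an empty record list")
    scores = rankdata([r.docking_score for r in records], method="min")
    vdw = rankdata([-r.vdw_contacts for r in records], method="min")
    bsa = rankdata([-r.bsa for r in records], method="min")
    keyed = sorted(
        zip(scores + vdw + bsa, records),
        key=lambda t: (t[0], t[1].docking_score, t[1].molecule_id),
    )
    return [r for _, r in keyed]


def filter_and_count(records: list[PoseRecord],
                     thresholds: LabelThresholds = BEST_WORST_THRESHOLDS
                     ) -> dict[str, int]:
    """Tally Best/Worst/neither labels over a record list."""
    counts = {BEST: 0, WORST: 0, NEITHER: 0}
    for rec in records:
        counts[label_best_worst(rec, thresholds)] += 1
    return counts
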