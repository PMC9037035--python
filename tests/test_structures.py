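"""Complex parsing, interface detection, and the frozen alanine scan."""

import math

import numpy as np
import pytest

import ppiscreen as pp
from ppiscreen.structures import binding_affinity, pair_affinity

TOY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   LEU A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  LEU A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  LEU A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      8  CG  LEU A   2       6.300   3.900   0.000  1.00  0.00           C
ATOM      9  C   LEU A   2       3.500   3.700   1.100  1.00  0.00           C
ATOM     10  O   LEU A   2       3.200   3.200   2.200  1.00  0.00           O
ATOM     11  C1  LIG B   1       8.000   4.500   0.000  1.00  0.00           C
ATOM     12  C2  LIG B   1       9.400   4.500   0.000  1.00  0.00           C
ATOM     13  O1  LIG B   1      10.100   5.700   0.000  1.00  0.00           O
ATOM     14  C3  LIG B   1      20.000  20.000  20.000  1.00  0.00           C
ATOM     15  C4  LIG B   1      21.400  20.000  20.000  1.00  0.00           C
ATOM     16  C5  LIG B   1      22.800  20.000  20.000  1.00  0.00           C
ATOM     17  C6  LIG B   1      24.200  20.000  20.000  1.00  0.00           C
ATOM     18  C7  LIG B   1      25.600  20.000  20.000  1.00  0.00           C
ATOM     19  C8  LIG B   1      27.000  20.000  20.000  1.00  0.00           C
ATOM     20  C9  LIG B   1      28.400  20.000  20.000  1.00  0.00           C
END
"""


class TestParseComplex:
    def test_two_chain_toy_counts(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        assert len(cx.atoms) == 20
        assert cx.receptor_chains == {"A"}
        assert cx.partner_chains == {"B"}
        assert all(a.vdw_radius > 0 for a in cx.atoms)

    def test_missing_partner_chain_is_configuration_error(self):
        with pytest.raises(pp.ConfigurationError, match="Z"):
            pp.parse_complex(TOY_PDB, ["A"], ["Z"])

    def test_unknown_element_named_in_error(self):
        bad = TOY_PDB.replace(
            "ATOM     11  C1  LIG B   1       8.000   4.500   0.000  1.00  0.00           C",
            "ATOM     11 XX1  LIG B   1       8.000   4.500   0.000  1.00  0.00          XX",
        )
        with pytest.raises(pp.PDBFormatError, match="[Xx]"):
            pp.parse_complex(bad, ["A"], ["B"])

    def test_waters_discarded(self):
        wet = TOY_PDB.replace(
            "END",
            "HETATM   21  O   HOH A  90      50.000  50.000  50.000  1.00  0.00           O\nEND",
        )
        cx = pp.parse_complex(wet, ["A"], ["B"])
        assert len(cx.atoms) == 20

    def test_overlapping_chain_sets_rejected(self):
        with pytest.raises(pp.ConfigurationError):
            pp.parse_complex(TOY_PDB, ["A", "B"], ["B"])


class TestInterfaceResidues:
    def test_close_residue_included_far_excluded(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        # LEU2 CG at (6.3, 3.9) is 1.8 A from ligand C1 (8.0, 4.5)
        assert pp.interface_residues(cx, cutoff=4.5) == [("A", 2, "LEU")]

    def test_far_complex_empty(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        shifted = cx.transformed(np.eye(3), np.zeros(3))
        only_far = pp.Complex(
            [a for a in shifted.atoms if a.chain_id == "A" or a.coords[0] > 19],
            {"A"}, {"B"},
        )
        assert pp.interface_residues(only_far, cutoff=4.5) == []

    def test_matches_brute_force_scan(self):
        from conftest import random_cloud_complex

        rng = np.random.default_rng(42)
        for _ in range(10):
            cx = random_cloud_complex(rng)
            cutoff = rng.uniform(2.0, 6.0)
            rec = [a for a in cx.receptor_atoms() if a.is_heavy]
            par = [a for a in cx.partner_atoms() if a.is_heavy]
            expected = sorted(
                {
                    a.residue_id
                    for a in rec
                    for b in par
                    if math.dist(a.coords, b.coords) <= cutoff
                },
                key=lambda r: (r[0], r[1]),
            )
            assert pp.interface_residues(cx, cutoff) == expected

    def test_monotone_in_cutoff(self):
        from conftest import random_cloud_complex

        cx = random_cloud_complex(np.random.default_rng(7))
        previous: set = set()
        for cutoff in (2.0, 3.0, 4.5, 6.0, 9.0):
            current = set(pp.interface_residues(cx, cutoff))
            assert previous <= current
            previous = current

    def test_rejects_nonpositive_cutoff(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        with pytest.raises(pp.ConfigurationError):
            pp.interface_residues(cx, 0.0)


class TestAlanineScan:
    def test_glycine_is_zero_by_convention(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        res = pp.alanine_scan(cx, ("A", 1, "GLY"))
        assert res.delta_affinity == 0.0
        assert not res.is_hot_spot

    def test_distant_side_chain_is_zero(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        far = cx.transformed(np.eye(3), np.zeros(3))
        moved = pp.Complex(
            [a if a.chain_id == "A"
             else type(a)(**{**a.__dict__, "coords": (a.coords[0] + 100, *a.coords[1:])})
             for a in far.atoms],
            {"A"}, {"B"},
        )
        assert pp.alanine_scan(moved, ("A", 2, "LEU")).delta_affinity == 0.0

    def test_additivity_over_eliminated_pairs(self):
        """Delta affinity equals the brute-force sum of removed pairwise terms."""
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        params = pp.EnergyParams()
        removed = [a for a in cx.residue_atoms(("A", 2, "LEU")) if a.name == "CG"]
        expected = sum(
            pair_affinity(a, b, params) for a in removed for b in cx.partner_atoms()
        )
        got = pp.alanine_scan(cx, ("A", 2, "LEU"), params).delta_affinity
        assert got == pytest.approx(expected, abs=1e-9)

    def test_single_contact_pair_equals_pair_term(self, toy_complex):
        cx, _ = toy_complex
        params = pp.EnergyParams()
        for residue in pp.interface_residues(cx):
            removed = [
                a for a in cx.residue_atoms(residue)
                if a.name not in {"N", "CA", "C", "O", "CB"}
            ]
            expected = sum(
                pair_affinity(a, b, params)
                for a in removed for b in cx.partner_atoms()
            )
            got = pp.alanine_scan(cx, residue, params).delta_affinity
            if residue[2] in ("GLY", "ALA"):
                expected = 0.0
            assert got == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        theta = 0.83
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = cx.transformed(rot, np.array([5.0, -3.0, 11.0]))
        before = pp.alanine_scan(cx, ("A", 2, "LEU")).delta_affinity
        after = pp.alanine_scan(moved, ("A", 2, "LEU")).delta_affinity
        assert after == pytest.approx(before, abs=1e-9)

    def test_partner_residue_rejected(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        with pytest.raises(pp.ConfigurationError):
            pp.alanine_scan(cx, ("B", 1, "LIG"))

    def test_absent_residue_is_lookup_error(self):
        cx = pp.parse_complex(TOY_PDB, ["A"], ["B"])
        with pytest.raises(pp.ResidueNotFoundError):
            pp.alanine_scan(cx, ("A", 99, "LEU"))


class TestCallHotSpots:
    def test_threshold_application(self):
        scan = [
            pp.ResidueScanResult(("A", 87, "ARG"), 7.2, True),
            pp.ResidueScanResult(("A", 44, "TYR"), 4.0, True),
            pp.ResidueScanResult(("A", 81, "LEU"), 3.9, False),
        ]
        assert pp.call_hot_spots(scan, 4.0) == [("A", 44, "TYR"), ("A", 87, "ARG")]

    def test_all_below_threshold_empty(self):
        scan = [pp.ResidueScanResult(("A", 1, "SER"), 0.5, False)]
        assert pp.call_hot_spots(scan, 4.0) == []
        assert pp.call_hot_spots([], 4.0) == []

    def test_matches_elementwise_filter_and_nests_by_threshold(self):
        rng = np.random.default_rng(3)
        scan = [
            pp.ResidueScanResult(("A", i, "LEU"), float(v), v >= 4.0)
            for i, v in enumerate(rng.uniform(0, 10, 20))
        ]
        for threshold in (1.0, 4.0, 7.5):
            expected = sorted(
                (r.residue for r in scan if r.delta_affinity >= threshold),
                key=lambda r: (r[0], r[1]),
            )
            assert pp.call_hot_spots(scan, threshold) == expected
        assert set(pp.call_hot_spots(scan, 7.5)) <= set(pp.call_hot_spots(scan, 4.0))

    def test_binding_affinity_empty_sides(self):
        assert binding_affinity([], [], pp.EnergyParams()) == 0.0
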