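import warnings

import numpy as np
import pytest

import ppiscreen as pp


@pytest.fixture(autouse=True)
def _quiet_modeling_warnings():
    """Training on small or pure-noise tables legitimately warns; keep logs clean."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no filter at the MCC floor.*")
        warnings.filterwarnings("ignore", message=".*single bin.*")
        yield


@pytest.fixture
def toy_complex():
    """Toy complex with 1 planted H-bond (residue 2) and 3+2 planted contacts."""
    spec = pp.ComplexSpec(
        n_receptor_residues=5,
        planted_hbond_residues=frozenset({2}),
        planted_contact_counts={3: 3, 4: 2},
        ligand_atom_count=3,
        seed=11,
    )
    return pp.make_toy_complex(spec)


@pytest.fixture
def planted_table():
    """137-molecule learning set, 3 informative of 50 descriptors, 2-SD shift."""
    return pp.make_learning_set(pp.LearningSetSpec(seed=5))


def random_cloud_complex(rng, n_per_side=25, box=12.0):
    """Random two-chain atom cloud (no planted structure) for oracle tests."""
    elements = np.array(["C", "N", "O", "S"])
    atoms = []
    idx = 0
    for chain, resbase in (("A", 1), ("B", 100)):
        for i in range(n_per_side):
            el = str(rng.choice(elements, p=[0.6, 0.15, 0.2, 0.05]))
            atoms.append(
                pp.Atom(
                    id=idx,
                    name=f"{el}{i}",
                    element=el,
                    coords=tuple(rng.uniform(0, box, 3)),
                    residue_name="UNK",
                    residue_number=resbase + i // 5,
                    chain_id=chain,
                    vdw_radius={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}[el],
                    partial_charge=0.0,
                )
            )
            idx += 1
    return pp.Complex(atoms, frozenset({"A"}), frozenset({"B"}))
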