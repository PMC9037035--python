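"""Fixed, versioned 2D molecular descriptor computation.

Descriptors come from RDKit's full 2D descriptor registry (~210 values:
constitutional, topological, and physicochemical), computed on canonicalized
structures so any valid spelling of the same molecule yields the same row.
The ordered descriptor-name list plus a digest forms a manifest; downstream
range-filter models embed the manifest so scoring can verify it operates on
the same descriptor space it was trained on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import ConfigurationError

RDLogger.DisableLog("rdApp.*")

#: Ordered descriptor names of the current manifest version.
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors._descList)


def manifest_hash(names=DESCRIPTOR_NAMES) -> str:
    """Digest identifying an ordered descriptor set."""
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


@dataclass
class DescriptorTable:
    """Molecules-by-descriptors matrix with optional Best/Worst labels."""

    values: pd.DataFrame  # index: molecule ids; columns: descriptor names
    labels: pd.Series | None = None  # optional, aligned with values.index
    errors: dict[str, str] = field(default_factory=dict)  # molecule id -> reason

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ConfigurationError("descriptor names must be unique")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def hash(self) -> str:
        return manifest_hash(tuple(self.values.columns))


def compute_descriptors(molecules, min_mw: float | None = None) -> DescriptorTable:
    """Compute the descriptor table for (id, SMILES) pairs or RDKit mols.

    ``molecules`` is an iterable of ``(molecule_id, smiles)`` pairs or of
    ``(molecule_id, rdkit.Chem.Mol)``.  Unparseable structures become error
    entries and the run continues; if *every* structure fails, raises.
    ``min_mw`` optionally drops molecules at or below a molecular-weight
    floor (g/mol), mirroring screening libraries restricted to larger
    ligands that can span a whole binding site.
    """
    rows: dict[str, list[float]] = {}
    errors: dict[str, str] = {}
    for mol_id, struct in molecules:
        mol = Chem.MolFromSmiles(struct) if isinstance(struct, str) else struct
        if mol is None:
            errors[str(mol_id)] = f"unparseable structure: {struct!r}"
            continue
        desc = Descriptors.CalcMolDescriptors(mol)
        if min_mw is not None and desc["MolWt"] <= min_mw:
            errors[str(mol_id)] = f"molecular weight {desc['MolWt']:.1f} <= {min_mw}"
            continue
        rows[str(mol_id)] = [float(desc[name]) for name in DESCRIPTOR_NAMES]
    if not rows:
        raise ConfigurationError("no molecule yielded descriptors; "
                                 f"{len(errors)} failures")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(DESCRIPTOR_NAMES))
    frame = frame.replace([np.inf, -np.inf], np.nan).dropna(axis=1)
    return DescriptorTable(values=frame, errors=errors)


def prune_descriptors(table: DescriptorTable, max_abs_corr: float = 0.99
                      ) -> DescriptorTable:
    """Drop uninformative and redundant columns, order-stably.

    Removes zero-variance columns, then from every pair with
    ``|Pearson r| > max_abs_corr`` removes the later-named (later-ordered)
    column.  Applying the pruning twice changes nothing.
    """
    if len(table.values) < 2:
        raise ConfigurationError("pruning requires at least two molecules")
    frame = table.values
    variable = frame.loc[:, frame.std(ddof=0) > 0.0]
    corr = variable.corr().abs().to_numpy()
    keep: list[int] = []
    for j in range(corr.shape[1]):
        if all(corr[j, i] <= max_abs_corr or np.isnan(corr[j, i]) for i in keep):
            keep.append(j)
    pruned = variable.iloc[:, keep]
    return DescriptorTable(values=pruned, labels=table.labels, errors=dict(table.errors))


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, ``SMILES [id]``."""
    pairs = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{n}"
            pairs.append((mol_id, smiles))
    return pairs


def read_sdf_file(path) -> list[tuple[str, "Chem.Mol"]]:
    """Read an SDF file into (id, mol) pairs; unparseable entries become None mols."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for n, mol in enumerate(supplier, 1):
        if mol is None:
            out.append((f"sdf{n}", None))
        else:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{n}"
            out.append((name, mol))
    return out
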