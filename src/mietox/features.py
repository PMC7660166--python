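"""Molecular descriptors and the shared training/prediction feature schema.

Each compound's minimum-energy conformer is summarised by the full
RDKit 2D descriptor block plus the 3D shape descriptors (principal
moments of inertia, asphericity, radius of gyration, ...).  Training
fixes a schema — the ordered list of retained descriptor columns and
their training means — which prediction-time matrices are aligned to,
so a model never sees columns in a different order or scale regime
than it was trained on.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, Descriptors3D

from .structprep import Conformer3D, read_sdf

__all__ = [
    "DescriptorSchema",
    "DescriptorMatrix",
    "EmptyDatasetError",
    "compute_descriptors",
    "build_descriptor_matrix",
    "clean_and_align",
    "write_descriptor_csv",
    "read_descriptor_csv",
]


class EmptyDatasetError(ValueError):
    """No compounds to compute descriptors for."""


@dataclass
class DescriptorSchema:
    """Ordered retained descriptors and their training means (for imputation)."""

    names: list[str]
    means: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"names": self.names, "means": self.means}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DescriptorSchema":
        data = json.loads(Path(path).read_text())
        return cls(names=list(data["names"]), means=dict(data["means"]))


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors; ``schema`` is set once cleaned/aligned.

    ``low_quality`` lists prediction compounds that were missing more
    than half of the schema columns before imputation.
    """

    values: pd.DataFrame
    schema: DescriptorSchema | None = None
    low_quality: list[str] = field(default_factory=list)


def compute_descriptors(mol: Chem.Mol) -> dict[str, float]:
    """All 2D + 3D descriptors for one molecule with 3D coordinates.

    Individual descriptor failures become NaN cells rather than aborts.
    """
    values = Descriptors.CalcMolDescriptors(mol, missingVal=math.nan, silent=True)
    try:
        values.update(Descriptors3D.CalcMolDescriptors3D(mol))
    except Exception:
        values.update(
            {name: math.nan for name in _descriptor3d_names()}
        )
    return {k: float(v) if v is not None else math.nan for k, v in values.items()}


def _descriptor3d_names() -> list[str]:
    # probe once with a trivial molecule so failed compounds still get columns
    global _D3_NAMES
    if _D3_NAMES is None:
        probe = Chem.AddHs(Chem.MolFromSmiles("C"))
        from rdkit.Chem import AllChem

        AllChem.EmbedMolecule(probe, randomSeed=1)
        _D3_NAMES = list(Descriptors3D.CalcMolDescriptors3D(probe))
    return _D3_NAMES


_D3_NAMES: list[str] | None = None


def build_descriptor_matrix(
    cs: list[Conformer3D] | list[Chem.Mol] | str | Path,
) -> DescriptorMatrix:
    """Raw descriptor matrix from conformers (a list or an SDF path).

    Every record must carry 3D coordinates; one row per compound,
    indexed by compound ID.
    """
    if isinstance(cs, (str, Path)):
        cs = read_sdf(cs)
    if not cs:
        raise EmptyDatasetError("no conformers to featurize")
    rows = {}
    for i, item in enumerate(cs):
        if isinstance(item, Conformer3D):
            mol, mol_id = item.mol, item.mol_id or f"MOL{i + 1}"
        else:
            mol = item
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"MOL{i + 1}"
        if mol.GetNumConformers() == 0:
            raise ValueError(f"compound {mol_id} has no 3D coordinates")
        rows[mol_id] = compute_descriptors(mol)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "SID"
    return DescriptorMatrix(values=frame)


def clean_and_align(
    raw: DescriptorMatrix, schema: DescriptorSchema | None = None
) -> DescriptorMatrix:
    """Clean a raw matrix (training) or align it to a schema (prediction).

    Training mode (no schema): drop every column containing a
    non-finite value or constant across rows, then record the retained
    column order and per-column means.  Prediction mode: subset and
    reorder to the schema, imputing missing cells with the stored
    training means; rows missing more than half the schema columns are
    flagged low-quality (still imputed and returned).
    """
    frame = raw.values
    if frame.empty:
        raise EmptyDatasetError("empty descriptor matrix")
    if schema is None:
        finite = frame.replace([np.inf, -np.inf], np.nan)
        keep = finite.columns[finite.notna().all(axis=0) & (finite.nunique(axis=0) > 1)]
        cleaned = finite[keep].astype(float)
        out_schema = DescriptorSchema(
            names=[str(c) for c in keep],
            means={str(c): float(cleaned[c].mean()) for c in keep},
        )
        return DescriptorMatrix(values=cleaned, schema=out_schema)

    aligned = frame.reindex(columns=schema.names).replace([np.inf, -np.inf], np.nan)
    missing_frac = aligned.isna().mean(axis=1)
    low_quality = [str(i) for i in aligned.index[missing_frac > 0.5]]
    if low_quality:
        warnings.warn(
            f"{len(low_quality)} compound(s) missing >50% of schema descriptors",
            stacklevel=2,
        )
    filled = aligned.fillna(pd.Series(schema.means))
    return DescriptorMatrix(values=filled.astype(float), schema=schema, low_quality=low_quality)


def write_descriptor_csv(matrix: DescriptorMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, index_label="SID")


def read_descriptor_csv(path: str | Path) -> DescriptorMatrix:
    frame = pd.read_csv(path, index_col="SID")
    return DescriptorMatrix(values=frame)
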