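"""Batch prediction: structures in, per-target scored calls out.

For each input compound the full pipeline runs: standardize ->
minimum-energy conformer -> descriptors -> align to each model's
schema -> raw probability x_u -> cutoff-anchored normalized score
x_n -> binary call (active iff x_n >= 0.5, i.e. x_u >= cutoff) ->
display bin (high > 0.6, low < 0.4, else ambiguous) -> applicability-
domain reliability.  A compound that fails to parse contributes one
error row and the batch continues.  With a full bundle (59 targets x
2 criteria) each valid compound yields 118 prediction entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admain, evaluation, features, structprep
from .model_pipeline import TargetBundle
from .qhts_labels import TargetRegistry, load_target_registry

__all__ = [
    "PredictionReport",
    "enumerate_model_slots",
    "load_bundles",
    "predict_batch",
    "display_bin",
    "write_report_csv",
    "write_report_sdf",
]

REPORT_COLUMNS = [
    "compound_id",
    "aid",
    "abbreviation",
    "criterion",
    "probability",
    "normalized_score",
    "call",
    "display_bin",
    "reliability",
    "conformer_method",
    "error",
]

BIN_HIGH = 0.6
BIN_LOW = 0.4


def display_bin(x_n: float) -> str:
    """Display bin for a normalized score: high / low / ambiguous."""
    if x_n > BIN_HIGH:
        return "high"
    if x_n < BIN_LOW:
        return "low"
    return "ambiguous"


def enumerate_model_slots(
    registry: TargetRegistry | None = None, criteria=(40, 1)
) -> list[tuple[int, int]]:
    """All (aid, criterion) model slots a full bundle must fill.

    With the packaged 59-target registry and both criteria this is the
    full complement of 118 models.
    """
    registry = registry or load_target_registry()
    return [(aid, c) for aid in registry.aids for c in criteria]


def load_bundles(
    bundle_dir: str | Path,
    registry: TargetRegistry | None = None,
    require_complete: bool = True,
) -> dict[tuple[int, int], TargetBundle]:
    """Load every per-target bundle under ``bundle_dir``.

    Bundle subdirectories are named ``<aid>_c<criterion>``.  With
    ``require_complete`` every registered slot must be present.
    """
    bundle_dir = Path(bundle_dir)
    bundles: dict[tuple[int, int], TargetBundle] = {}
    for sub in sorted(bundle_dir.iterdir()):
        if sub.is_dir() and (sub / "meta.json").exists():
            bundle = TargetBundle.load(sub)
            bundles[(bundle.aid, bundle.criterion)] = bundle
    if require_complete:
        missing = [s for s in enumerate_model_slots(registry) if s not in bundles]
        if missing:
            raise FileNotFoundError(
                f"bundle directory is missing {len(missing)} model slot(s), "
                f"e.g. {missing[:3]}"
            )
    return bundles


@dataclass
class PredictionReport:
    """Long-format prediction results plus per-compound conformers."""

    frame: pd.DataFrame
    conformers: list[structprep.Conformer3D] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return int(self.frame["error"].notna().sum())


def _error_row(compound_id: str, message: str) -> dict:
    row = {col: np.nan for col in REPORT_COLUMNS}
    row["compound_id"] = compound_id
    row["error"] = message
    return row


def predict_batch(
    structures: list[tuple[str, str]] | str | Path,
    bundles: dict[tuple[int, int], TargetBundle] | str | Path,
    seed: int = 0,
    n_candidates: int = 200,
    time_budget: float = 60.0,
    criteria=(40, 1),
    registry: TargetRegistry | None = None,
) -> PredictionReport:
    """Score a batch of structures against every loaded target model.

    ``structures`` is a list of (id, SMILES) pairs, a SMILES file path,
    or an SDF path.  ``bundles`` is a bundle directory or a preloaded
    mapping.  Invalid structures produce one flagged error row each;
    the rest of the batch is unaffected.
    """
    if isinstance(structures, (str, Path)):
        p = Path(structures)
        if p.suffix.lower() == ".sdf":
            confs = structprep.read_sdf(p)
            structures = [
                (c.mol_id, structprep.Chem.MolToSmiles(structprep.Chem.RemoveHs(c.mol)))
                for c in confs
            ]
        else:
            structures = structprep.read_smiles_file(p)
    if isinstance(bundles, (str, Path)):
        bundles = load_bundles(bundles, registry=registry, require_complete=False)
    registry = registry or load_target_registry()
    wanted = [
        (slot, bundle)
        for slot, bundle in sorted(bundles.items())
        if slot[1] in criteria
    ]
    if not wanted:
        raise ValueError("no bundles match the requested criteria")

    rows: list[dict] = []
    conformers: list[structprep.Conformer3D] = []
    for compound_id, smiles in structures:
        try:
            std = structprep.standardize_structure(smiles, mol_id=compound_id)
            conf = structprep.generate_conformer(
                std, n_candidates=n_candidates, time_budget=time_budget, seed=seed
            )
        except (structprep.InvalidStructureError, structprep.ConformerFailureError) as exc:
            rows.append(_error_row(compound_id, str(exc)))
            continue
        conformers.append(conf)
        raw = features.build_descriptor_matrix([conf])
        for (aid, criterion), bundle in wanted:
            aligned = features.clean_and_align(raw, schema=bundle.schema)
            x_row = aligned.values.iloc[[0]]
            x_u = float(bundle.selected.model.predict_proba(x_row)[0, 1])
            x_u = float(np.clip(x_u, 0.0, 1.0))
            x_n = evaluation.normalize_score(x_u, bundle.selected.cutoff)
            reliability = admain.reliability_score(x_row.iloc[0], bundle.ad)
            rows.append(
                {
                    "compound_id": compound_id,
                    "aid": aid,
                    "abbreviation": bundle.abbreviation
                    or str(registry.by_aid(aid)["abbreviation"]),
                    "criterion": criterion,
                    "probability": x_u,
                    "normalized_score": x_n,
                    "call": "active" if x_n >= 0.5 else "inactive",
                    "display_bin": display_bin(x_n),
                    "reliability": reliability,
                    "conformer_method": conf.method,
                    "error": np.nan,
                }
            )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return PredictionReport(frame=frame, conformers=conformers)


def write_report_csv(report: PredictionReport, path: str | Path) -> None:
    report.frame.to_csv(path, index=False)


def write_report_sdf(report: PredictionReport, path: str | Path) -> None:
    """SDF output: one record per compound, per-target scores as data fields."""
    from rdkit import Chem

    frame = report.frame[report.frame["error"].isna()]
    by_compound = {c.mol_id: c for c in report.conformers}
    writer = Chem.SDWriter(str(path))
    try:
        for compound_id, group in frame.groupby("compound_id", sort=False):
            conf = by_compound.get(str(compound_id))
            if conf is None:
                continue
            mol = Chem.Mol(conf.mol)
            mol.SetProp("_Name", str(compound_id))
            for _, row in group.iterrows():
                key = f"{row['abbreviation']}_c{row['criterion']}"
                mol.SetProp(f"{key}_score", f"{row['normalized_score']:.4f}")
                mol.SetProp(f"{key}_call", str(row["call"]))
                mol.SetProp(f"{key}_reliability", f"{row['reliability']:.4f}")
            writer.write(mol)
    finally:
        writer.close()
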