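"""Synthetic data generators: score tables, descriptor datasets, toy molecules.

These make every pipeline stage testable without downloading assay
data.  Score tables mimic qHTS semantics (inactives at 0, actives at
or above the generating criterion, an optional inconclusive band at
5-30) with the screening campaign's typical class imbalance — on
average about 4.7% of compounds are active under the criterion of 40.
Descriptor datasets are two multivariate-Gaussian classes separated by
a standardized mean shift d along a random direction, which gives a
closed-form Bayes AUC of Phi(d / sqrt(2)) for calibrating what a good
model can achieve.  All generators are pure functions of their
arguments, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDatasetSpec",
    "DEFAULT_ACTIVE_RATIO",
    "synth_score_table",
    "synth_descriptor_dataset",
    "toy_molecule_set",
    "bayes_auc",
]

#: Mean fraction of active compounds under the criterion of 40 in the
#: modelled screening campaign.
DEFAULT_ACTIVE_RATIO = 0.047


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters shared by the generators."""

    n_compounds: int = 500
    n_features: int = 30
    effect_size: float = 1.0  # standardized mean shift d between classes
    active_ratio: float = DEFAULT_ACTIVE_RATIO
    seed: int = 0
    inconclusive_fraction: float = 0.0  # of inactives, given scores 5-30

    def __post_init__(self) -> None:
        if not 0.0 < self.active_ratio < 1.0:
            raise ValueError("active_ratio must lie strictly inside (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect size must be nonnegative")


def bayes_auc(effect_size: float) -> float:
    """Optimal achievable AUC for the two-Gaussian class model."""
    from scipy.stats import norm  # local import; scipy only needed here

    return float(norm.cdf(effect_size / np.sqrt(2.0)))


def synth_score_table(
    spec: SyntheticDatasetSpec,
    aids=(720516,),
    criterion: int = 40,
) -> pd.DataFrame:
    """Synthetic SID x AID activity-score table.

    Per assay, each compound is active with probability
    ``spec.active_ratio``; actives get integer scores uniform on
    [criterion, 100], inactives score 0 except for an optional
    inconclusive fraction scored uniform on [5, 30] (meaningful when
    generating under the criterion of 40).
    """
    rng = np.random.default_rng(spec.seed)
    sids = [f"S{i:06d}" for i in range(1, spec.n_compounds + 1)]
    data = {}
    for aid in aids:
        active = rng.random(spec.n_compounds) < spec.active_ratio
        scores = np.zeros(spec.n_compounds)
        scores[active] = rng.integers(criterion, 101, size=int(active.sum()))
        if spec.inconclusive_fraction > 0:
            inactive_idx = np.flatnonzero(~active)
            n_inc = int(round(spec.inconclusive_fraction * inactive_idx.size))
            chosen = rng.choice(inactive_idx, size=n_inc, replace=False)
            scores[chosen] = rng.integers(5, 31, size=n_inc)
        data[str(aid)] = scores
    table = pd.DataFrame(data, index=pd.Index(sids, name="SID"))
    return table


def synth_descriptor_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labelled descriptor matrix with a two-Gaussian class signal.

    Features are standard normal; active compounds are shifted by
    ``spec.effect_size`` along a random unit direction.  Labels are
    imbalanced per ``spec.active_ratio``.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_compounds) < spec.active_ratio).astype(int)
    direction = rng.normal(size=spec.n_features)
    direction /= np.linalg.norm(direction)
    X = rng.normal(size=(spec.n_compounds, spec.n_features))
    X[y == 1] += spec.effect_size * direction
    sids = pd.Index([f"S{i:06d}" for i in range(1, spec.n_compounds + 1)], name="SID")
    cols = [f"D{j:04d}" for j in range(1, spec.n_features + 1)]
    return (
        pd.DataFrame(X, index=sids, columns=cols),
        pd.Series(y, index=sids, name="label"),
    )


def toy_molecule_set() -> list[tuple[str, str]]:
    """~20 small molecules covering standardization and 3D edge cases.

    Includes salt pairs and charged species (to exercise fragment
    stripping and neutralization); everything parses, standardizes and
    embeds in 3D without the fallback path at default budgets.
    """
    return [
        ("ethanol", "CCO"),
        ("ethanol_hcl_salt", "CCO.Cl"),
        ("sodium_acetate", "CC(=O)[O-].[Na+]"),
        ("ammonium_benzoate", "[NH4+].c1ccccc1C(=O)[O-]"),
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("phenol", "Oc1ccccc1"),
        ("aniline", "Nc1ccccc1"),
        ("anilinium", "[NH3+]c1ccccc1"),
        ("acetic_acid", "CC(=O)O"),
        ("acetamide", "CC(N)=O"),
        ("pyridine", "c1ccncc1"),
        ("cyclohexane", "C1CCCCC1"),
        ("isopropanol", "CC(C)O"),
        ("dimethyl_ether", "COC"),
        ("acetone", "CC(C)=O"),
        ("methylamine", "CN"),
        ("chlorobenzene", "Clc1ccccc1"),
        ("furan", "c1ccoc1"),
        ("thiophene", "c1ccsc1"),
        ("nitromethane", "C[N+](=O)[O-]"),
        ("butyric_acid", "CCCC(=O)O"),
        ("styrene", "C=Cc1ccccc1"),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ]
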