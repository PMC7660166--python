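"""The validator/recorder/filter modelling scheme.

Per target and label criterion: 10% of compounds are held out as the
test set; the remaining development set is partitioned into three
disjoint out-of-fold (OOF) thirds.  For each OOF allocation (train on
two thirds, validate on the held-out third) a gradient-boosted tree
classifier (XGBoost) is trained at each of 100 learning rates
0.01 x {0..99}, every other hyperparameter at library defaults.  The
recorder keeps all 3 x 100 = 300 fitted models with their validation
AUCs.  The filter drops learning rates whose across-fold AUC standard
deviation exceeds ``sd_max`` (overfitting / unstable settings), then
selects the single highest-AUC surviving record, breaking ties toward
the lower learning rate and then the lower fold index.

The selected model's operating cutoff is the Youden threshold computed
on the untouched test split, mirroring the original workflow (this
uses test data to set the cutoff — see the methods note; OOF-based
thresholding is available via ``threshold_on="oof"``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from . import evaluation
from .admain import ADReference, fit_ad
from .features import DescriptorSchema

__all__ = [
    "SplitPlan",
    "HyperparameterGrid",
    "ModelRecord",
    "SelectedModel",
    "TargetBundle",
    "ConstantScorer",
    "split_dataset",
    "run_validator",
    "learning_rate_sds",
    "filter_survivors",
    "apply_filter",
    "train_target",
]

TEST_FRACTION = 0.10
K_FOLDS = 3
SD_MAX = 0.05
GRID_SIZE = 100


@dataclass
class SplitPlan:
    """Test/development allocation and the OOF fold partition of dev."""

    test_ids: list
    dev_ids: list
    folds: list[list]
    seed: int

    def __post_init__(self) -> None:
        test, dev = set(self.test_ids), set(self.dev_ids)
        if test & dev:
            raise ValueError("test and development sets overlap")
        fold_sets = [set(f) for f in self.folds]
        union: set = set()
        for fs in fold_sets:
            if union & fs:
                raise ValueError("folds are not pairwise disjoint")
            union |= fs
        if union != dev:
            raise ValueError("folds do not cover the development set")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


def split_dataset(
    ids,
    test_fraction: float = TEST_FRACTION,
    k_folds: int = K_FOLDS,
    seed: int = 0,
) -> SplitPlan:
    """Random test/dev split plus a balanced k-fold partition of dev.

    Simple random (unstratified) allocation, deterministic in ``seed``;
    10% of all compounds go to the test set and the development folds
    differ in size by at most one.
    """
    ids = list(ids)
    if len(ids) < k_folds + 1:
        raise ValueError(f"need at least {k_folds + 1} compounds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    n_test = min(n_test, len(ids) - k_folds)  # folds must be nonempty
    test_ids = [ids[i] for i in order[:n_test]]
    dev_ids = [ids[i] for i in order[n_test:]]
    folds = [list(part) for part in np.array_split(np.array(dev_ids, dtype=object), k_folds)]
    return SplitPlan(test_ids=test_ids, dev_ids=dev_ids, folds=folds, seed=seed)


@dataclass
class HyperparameterGrid:
    """Learning-rate grid; all other learner settings stay at defaults."""

    learning_rates: tuple[float, ...] = tuple(round(0.01 * i, 2) for i in range(GRID_SIZE))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(lr < 0 for lr in self.learning_rates):
            raise ValueError("learning rates must be nonnegative")


@dataclass
class ModelRecord:
    """One recorder entry: a fitted scorer and its validation AUC."""

    fold: int
    learning_rate: float
    model: XGBClassifier
    auc: float
    degenerate: bool = False  # single-class validation fold or constant scores


@dataclass
class SelectedModel:
    """The filter's output: one surviving record plus its provenance."""

    learning_rate: float
    model: XGBClassifier
    fold: int
    fold_aucs: list[float]
    auc_sd: float
    cutoff: float | None = None
    fallback_used: bool = False


class ConstantScorer:
    """Stand-in scorer for a training fold that drew a single class.

    Emits the class prior as a constant probability so the recorder
    stays complete (the record is flagged degenerate, AUC 0.5).
    """

    def __init__(self, p: float):
        self.p = float(np.clip(p, 1e-6, 1 - 1e-6))

    def predict_proba(self, X) -> np.ndarray:
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


def _new_learner(learning_rate: float, seed: int) -> XGBClassifier:
    return XGBClassifier(
        learning_rate=learning_rate,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        eval_metric="logloss",
    )


def _safe_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, bool]:
    """Validation AUC; single-class or constant-score folds -> 0.5, flagged."""
    if np.unique(y_true).size < 2:
        return 0.5, True
    if np.allclose(scores, scores[0]):
        return 0.5, True
    _, auc = evaluation.compute_roc_auc(scores, y_true)
    return auc, False


def run_validator(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    grid: HyperparameterGrid | None = None,
) -> list[ModelRecord]:
    """Grid-train over every (fold, learning rate) pair; return all records.

    For each OOF allocation the model trains on the other two thirds
    and is scored by ROC-AUC on its held-out third.  Always returns
    k_folds x |grid| records.
    """
    grid = grid or HyperparameterGrid()
    records: list[ModelRecord] = []
    fold_data = []
    for f, fold_ids in enumerate(plan.folds):
        train_ids = [i for other in plan.folds if other is not plan.folds[f] for i in other]
        X_tr, y_tr = X.loc[train_ids], y.loc[train_ids].to_numpy()
        X_va, y_va = X.loc[fold_ids], y.loc[fold_ids].to_numpy()
        fold_data.append((X_tr, y_tr, X_va, y_va))
    for lr in grid.learning_rates:
        for f, (X_tr, y_tr, X_va, y_va) in enumerate(fold_data):
            if np.unique(y_tr).size < 2:
                model = ConstantScorer(float(np.mean(y_tr)))
            else:
                model = _new_learner(lr, grid.seed)
                model.fit(X_tr, y_tr)
            scores = model.predict_proba(X_va)[:, 1]
            auc, degenerate = _safe_auc(y_va, scores)
            records.append(
                ModelRecord(fold=f, learning_rate=lr, model=model, auc=auc,
                            degenerate=degenerate)
            )
    return records


def _records_by_rate(records: list[ModelRecord]) -> dict[float, list[ModelRecord]]:
    by_lr: dict[float, list[ModelRecord]] = {}
    for rec in records:
        by_lr.setdefault(rec.learning_rate, []).append(rec)
    return by_lr


def learning_rate_sds(records: list[ModelRecord]) -> dict[float, float]:
    """Across-fold sample SD of validation AUC per learning rate."""
    return {
        lr: float(np.std([r.auc for r in recs], ddof=1)) if len(recs) > 1 else 0.0
        for lr, recs in _records_by_rate(records).items()
    }


def filter_survivors(records: list[ModelRecord], sd_max: float = SD_MAX) -> list[float]:
    """Learning rates whose across-fold AUC SD does not exceed ``sd_max``."""
    sds = learning_rate_sds(records)
    return [lr for lr, sd in sds.items() if sd <= sd_max]


def apply_filter(records: list[ModelRecord], sd_max: float = SD_MAX) -> SelectedModel:
    """Exclude unstable learning rates, then pick the best record.

    A learning rate is excluded when the sample standard deviation of
    its across-fold validation AUCs exceeds ``sd_max``.  Among the
    surviving records the single highest AUC wins; ties break toward
    the lower learning rate, then the lower fold index.  If every rate
    is excluded, the smallest-SD rate is used instead with a warning —
    the filter never returns nothing.
    """
    if not records:
        raise ValueError("no records to filter")
    by_lr = _records_by_rate(records)
    sds = learning_rate_sds(records)
    survivors = filter_survivors(records, sd_max)
    fallback_used = False
    if not survivors:
        best_sd_lr = min(sds, key=lambda lr: (sds[lr], lr))
        warnings.warn(
            f"all learning rates exceeded sd_max={sd_max}; falling back to the "
            f"smallest-SD rate {best_sd_lr} (sd={sds[best_sd_lr]:.4f})",
            stacklevel=2,
        )
        survivors = [best_sd_lr]
        fallback_used = True
    pool = [r for lr in survivors for r in by_lr[lr]]
    best = max(pool, key=lambda r: (r.auc, -r.learning_rate, -r.fold))
    return SelectedModel(
        learning_rate=best.learning_rate,
        model=best.model,
        fold=best.fold,
        fold_aucs=[r.auc for r in sorted(by_lr[best.learning_rate], key=lambda r: r.fold)],
        auc_sd=sds[best.learning_rate],
        fallback_used=fallback_used,
    )


@dataclass
class TargetBundle:
    """Everything needed to score one target x criterion at prediction time."""

    aid: int
    criterion: int
    selected: SelectedModel
    schema: DescriptorSchema
    ad: ADReference
    test_metrics: evaluation.MetricSet
    seed: int
    abbreviation: str = ""

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory) / f"{self.aid}_c{self.criterion}"
        directory.mkdir(parents=True, exist_ok=True)
        if isinstance(self.selected.model, ConstantScorer):
            (directory / "model_constant.json").write_text(
                json.dumps({"p": self.selected.model.p})
            )
        else:
            # persist the booster; the sklearn wrapper reconstructs from it
            self.selected.model.get_booster().save_model(directory / "model.json")
        self.schema.to_json(directory / "schema.json")
        self.ad.save(directory / "ad")
        meta = {
            "aid": self.aid,
            "criterion": self.criterion,
            "abbreviation": self.abbreviation,
            "learning_rate": self.selected.learning_rate,
            "fold": self.selected.fold,
            "fold_aucs": self.selected.fold_aucs,
            "auc_sd": self.selected.auc_sd,
            "cutoff": self.selected.cutoff,
            "filter_fallback": self.selected.fallback_used,
            "seed": self.seed,
            "test_metrics": {
                k: (None if np.isnan(v) else v)
                for k, v in self.test_metrics.as_dict().items()
            },
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TargetBundle":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if (directory / "model_constant.json").exists():
            model = ConstantScorer(
                json.loads((directory / "model_constant.json").read_text())["p"]
            )
        else:
            model = XGBClassifier()
            model.load_model(directory / "model.json")
        selected = SelectedModel(
            learning_rate=meta["learning_rate"],
            model=model,
            fold=meta["fold"],
            fold_aucs=meta["fold_aucs"],
            auc_sd=meta["auc_sd"],
            cutoff=meta["cutoff"],
            fallback_used=meta["filter_fallback"],
        )
        metrics = evaluation.MetricSet(
            **{k: (np.nan if v is None else v) for k, v in meta["test_metrics"].items()}
        )
        return cls(
            aid=meta["aid"],
            criterion=meta["criterion"],
            selected=selected,
            schema=DescriptorSchema.from_json(directory / "schema.json"),
            ad=ADReference.load(directory / "ad"),
            test_metrics=metrics,
            seed=meta["seed"],
            abbreviation=meta.get("abbreviation", ""),
        )


def train_target(
    X: pd.DataFrame,
    y: pd.Series,
    aid: int,
    criterion: int,
    seed: int = 0,
    grid: HyperparameterGrid | None = None,
    sd_max: float = SD_MAX,
    schema: DescriptorSchema | None = None,
    refit: bool = False,
    threshold_on: str = "test",
    abbreviation: str = "",
) -> TargetBundle:
    """Full per-target training: split, validate, filter, threshold, AD.

    ``X`` must already be cleaned (a schema is derived from it when not
    given).  ``threshold_on`` chooses where the Youden cutoff comes
    from: ``"test"`` (the original workflow) or ``"oof"`` (the selected
    model's own validation fold, leakage-free).  ``refit=True``
    retrains the selected learning rate on the full development set
    before thresholding.
    """
    common = X.index.intersection(y.index)
    X, y = X.loc[common], y.loc[common].astype(int)
    if y.nunique() < 2:
        raise ValueError(
            f"AID {aid} criterion {criterion}: labels contain a single class; "
            "no classifier can be trained"
        )
    plan = split_dataset(list(X.index), seed=seed)
    grid = grid or HyperparameterGrid(seed=seed)
    records = run_validator(X, y, plan, grid)
    selected = apply_filter(records, sd_max=sd_max)
    if refit:
        model = _new_learner(selected.learning_rate, grid.seed)
        model.fit(X.loc[plan.dev_ids], y.loc[plan.dev_ids].to_numpy())
        selected.model = model

    if threshold_on == "test":
        ids = plan.test_ids
    elif threshold_on == "oof":
        ids = plan.folds[selected.fold]
    else:
        raise ValueError("threshold_on must be 'test' or 'oof'")
    scores = selected.model.predict_proba(X.loc[ids])[:, 1]
    y_eval = y.loc[ids].to_numpy()
    metrics = evaluation.MetricSet()
    try:
        curve, auc = evaluation.compute_roc_auc(scores, y_eval)
        cutoff = evaluation.youden_threshold(curve)
        cutoff = float(np.clip(cutoff, 1e-6, 1 - 1e-6))  # keep Eq-form cutoff usable
        calls = (scores >= cutoff).astype(int)
        metrics = evaluation.compute_metrics(evaluation.confusion_counts(y_eval, calls))
        metrics.auc = auc
    except evaluation.UndefinedAUCError:
        warnings.warn(
            f"AID {aid} criterion {criterion}: evaluation split has a single "
            "class; cutoff defaults to 0.5 and test metrics are undefined",
            stacklevel=2,
        )
        cutoff = 0.5
        metrics.undefined = list(evaluation.METRIC_NAMES)
    selected.cutoff = cutoff

    if schema is None:
        schema = DescriptorSchema(
            names=[str(c) for c in X.columns],
            means={str(c): float(X[c].mean()) for c in X.columns},
        )
    train_ids = [i for i in plan.dev_ids]
    ad = fit_ad(X.loc[train_ids])
    return TargetBundle(
        aid=int(aid),
        criterion=int(criterion),
        selected=selected,
        schema=schema,
        ad=ad,
        test_metrics=metrics,
        seed=seed,
        abbreviation=abbreviation,
    )
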