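"""Applicability domain: 5-NN log-distance reliability and a PCA view.

A QSTR model is only trustworthy near its training chemistry.  Each
query is scored by the mean of the logarithmic Euclidean distances to
its five nearest training molecules in (z-standardized) descriptor
space.  That mean log-distance is mapped linearly onto [0, 1] using
the min/max of the training set's own leave-one-out values, then
inverted and clamped, so 1 means "indistinguishable from training
chemistry" and 0 means "far outside it".  A 2-component PCA of the
training matrix provides the chemical-space scatter used to eyeball a
query's position relative to the training cloud.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ADReference", "fit_ad", "reliability_score", "reliability_scores",
           "pca_project", "training_projection", "plot_chemical_space"]

K_NEIGHBORS = 5
LOG_EPS = 1e-8  # added before log so exact duplicates (distance 0) are defined


@dataclass
class ADReference:
    """Frozen training descriptor space for reliability scoring.

    ``cal_min``/``cal_max`` anchor the reliability scale: they are the
    extremes of the training leave-one-out mean log-distances.
    """

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray
    train_z: np.ndarray
    train_ids: list[str]
    cal_min: float
    cal_max: float
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (2, n_columns)
    explained_variance_ratio: np.ndarray
    k: int = K_NEIGHBORS

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            mean=self.mean,
            sd=self.sd,
            train_z=self.train_z,
            pca_mean=self.pca_mean,
            pca_components=self.pca_components,
            explained_variance_ratio=self.explained_variance_ratio,
        )
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "columns": self.columns,
                    "train_ids": self.train_ids,
                    "cal_min": self.cal_min,
                    "cal_max": self.cal_max,
                    "k": self.k,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ADReference":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            columns=meta["columns"],
            mean=arrays["mean"],
            sd=arrays["sd"],
            train_z=arrays["train_z"],
            train_ids=meta["train_ids"],
            cal_min=meta["cal_min"],
            cal_max=meta["cal_max"],
            pca_mean=arrays["pca_mean"],
            pca_components=arrays["pca_components"],
            explained_variance_ratio=arrays["explained_variance_ratio"],
            k=meta["k"],
        )


def _mean_log_knn(dists: np.ndarray, k: int) -> float:
    nearest = np.partition(dists, k - 1)[:k]
    return float(np.mean(np.log(nearest + LOG_EPS)))


def fit_ad(train, k: int = K_NEIGHBORS) -> ADReference:
    """Fit the applicability-domain reference on training descriptors.

    ``train`` is a DataFrame (or DescriptorMatrix) of cleaned training
    descriptors.  Constant columns are excluded from the distance
    space; the rest are z-standardized with training mean/SD.  Needs at
    least k + 1 compounds so leave-one-out neighbours exist.
    """
    from sklearn.decomposition import PCA

    frame = train if isinstance(train, pd.DataFrame) else train.values
    if len(frame) < k + 1:
        raise ValueError(f"applicability domain needs at least {k + 1} compounds")
    sd = frame.std(axis=0, ddof=0)
    keep = frame.columns[sd > 0]
    frame = frame[keep]
    mean = frame.mean(axis=0).to_numpy()
    sdv = frame.std(axis=0, ddof=0).to_numpy()
    z = (frame.to_numpy(dtype=float) - mean) / sdv

    n = z.shape[0]
    loo = np.empty(n)
    for i in range(n):
        d = np.linalg.norm(z - z[i], axis=1)
        d = np.delete(d, i)
        loo[i] = _mean_log_knn(d, k)
    cal_min, cal_max = float(loo.min()), float(loo.max())
    if cal_min >= cal_max:
        # pathological all-equidistant training set; widen so the scale exists
        cal_max = cal_min + 1e-12

    n_comp = min(2, n, z.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(z)
    components = np.zeros((2, z.shape[1]))
    components[:n_comp] = pca.components_
    evr = np.zeros(2)
    evr[:n_comp] = pca.explained_variance_ratio_

    return ADReference(
        columns=[str(c) for c in keep],
        mean=mean,
        sd=sdv,
        train_z=z,
        train_ids=[str(i) for i in frame.index],
        cal_min=cal_min,
        cal_max=cal_max,
        pca_mean=z.mean(axis=0),
        pca_components=components,
        explained_variance_ratio=evr,
        k=k,
    )


def _align_query(q, ref: ADReference) -> np.ndarray:
    if isinstance(q, pd.Series):
        missing = [c for c in ref.columns if c not in q.index]
        if missing:
            raise ValueError(f"query missing descriptor columns: {missing[:5]}")
        q = q[ref.columns].to_numpy(dtype=float)
    q = np.asarray(q, dtype=float)
    if q.shape != (len(ref.columns),):
        raise ValueError(
            f"query has {q.shape} values, reference expects {len(ref.columns)}"
        )
    return (q - ref.mean) / ref.sd


def reliability_score(q, ref: ADReference) -> float:
    """In-domain reliability of one query row, in [0, 1].

    reliability = clamp((cal_max - dbar) / (cal_max - cal_min), 0, 1)
    where dbar is the mean log-distance to the ``ref.k`` nearest
    training molecules.  Near-duplicates of training compounds score 1;
    far outliers score 0.
    """
    z = _align_query(q, ref)
    d = np.linalg.norm(ref.train_z - z, axis=1)
    dbar = _mean_log_knn(d, ref.k)
    rel = (ref.cal_max - dbar) / (ref.cal_max - ref.cal_min)
    return float(np.clip(rel, 0.0, 1.0))


def reliability_scores(queries: pd.DataFrame, ref: ADReference) -> pd.Series:
    """Reliability for every row of an aligned descriptor matrix."""
    return pd.Series(
        [reliability_score(queries.loc[i], ref) for i in queries.index],
        index=queries.index,
        name="reliability",
    )


def pca_project(q, ref: ADReference) -> np.ndarray:
    """Project a query row onto the top-2 training principal components."""
    z = _align_query(q, ref)
    return (z - ref.pca_mean) @ ref.pca_components.T


def training_projection(ref: ADReference) -> np.ndarray:
    """(n_train, 2) coordinates of the training cloud for plotting."""
    return (ref.train_z - ref.pca_mean) @ ref.pca_components.T


def plot_chemical_space(
    ref: ADReference, queries: pd.DataFrame | None = None, path: str | Path | None = None
):
    """Chemical-space scatter: training cloud in grey, queries in blue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    train_xy = training_projection(ref)
    ax.scatter(train_xy[:, 0], train_xy[:, 1], s=8, c="0.6", label="training set")
    if queries is not None and len(queries):
        q_xy = np.vstack([pca_project(queries.loc[i], ref) for i in queries.index])
        ax.scatter(q_xy[:, 0], q_xy[:, 1], s=30, c="tab:blue", label="query")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
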