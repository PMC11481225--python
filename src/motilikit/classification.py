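"""Assigning new cells to learned motility clusters.

The primary classifier is a multi-class linear SVM (one-vs-rest, hinge
loss) over the eight normalized motility parameters, trained on the k-means
cluster labels with a stratified 90:10 train/test split.  A nearest-centroid
rule (smallest Euclidean distance to a cluster centroid in z-score space)
serves as an independent cross-check.  Simulated cohorts are ground-truthed
by the augmented-reclustering rule: conceptually, re-cluster the training
set plus one new cell and read off its label — implemented efficiently as
assignment under the frozen k-means objective, with an exact warm-start
re-clustering mode available for small-scale verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from motilikit.aprw import fit_dataset
from motilikit.clustering import (
    ClusterModel,
    FeatureMatrix,
    NormalizationStats,
    _lloyd_correlation,
    _row_standardize,
    assign_clusters,
    normalize_features,
)
from motilikit.trajectory_io import TrajectorySet


@dataclass
class ClassifierBundle:
    """A trained linear max-margin classifier plus everything needed to
    score a new cell: coefficient matrix, normalization stats, labels and
    the train/test split record."""

    coef: np.ndarray  # (n_clusters, 8)
    intercept: np.ndarray  # (n_clusters,)
    classes: np.ndarray  # cluster indices, ascending
    stats: NormalizationStats
    split_fraction: float
    seed: int
    train_accuracy: float = np.nan
    test_accuracy: float = np.nan
    per_cluster_accuracy: pd.DataFrame | None = field(default=None, repr=False)

    def decision_function(self, values: np.ndarray) -> np.ndarray:
        return np.atleast_2d(values) @ self.coef.T + self.intercept

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Cluster indices for rows in normalized feature space."""
        scores = self.decision_function(values)
        return self.classes[scores.argmax(axis=1)]

    def to_json(self, path) -> None:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "classes": self.classes.tolist(),
            "stats": self.stats.to_dict(),
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierBundle":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            classes=np.asarray(d["classes"], dtype=int),
            stats=NormalizationStats.from_dict(d["stats"]),
            split_fraction=float(d["split_fraction"]),
            seed=int(d["seed"]),
            train_accuracy=float(d["train_accuracy"]),
            test_accuracy=float(d["test_accuracy"]),
        )


def _per_cluster_accuracy(
    truth: np.ndarray, pred: np.ndarray
) -> pd.DataFrame:
    rows = []
    for c in np.unique(truth):
        mask = truth == c
        rows.append(
            {
                "cluster": int(c),
                "n": int(mask.sum()),
                "accuracy": float((pred[mask] == c).mean()),
            }
        )
    return pd.DataFrame(rows)


def train_cluster_classifier(
    fm: FeatureMatrix,
    labels: np.ndarray | pd.Series,
    split: float = 0.9,
    seed: int = 0,
    C: float = 100.0,
) -> ClassifierBundle:
    """Train the multi-class linear hinge-loss SVM on cluster labels.

    Uses the Crammer-Singer multi-class hinge formulation: cluster labels
    produced by correlation-distance k-means are an argmax of linear scores
    in the normalized feature space, which this joint formulation can
    represent directly (independent one-vs-rest hinges underfit it badly).
    A stratified ``split`` : 1-split train/test partition is drawn; overall
    and per-cluster accuracy are reported on both partitions.  Clusters
    with a single cell cannot be stratified and are excluded.
    """
    y = np.asarray(labels, dtype=int)
    X = fm.array()
    counts = pd.Series(y).value_counts()
    usable = counts[counts >= 2].index
    keep = np.isin(y, usable)
    X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 clusters with >= 2 cells each")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )
    svm = LinearSVC(
        multi_class="crammer_singer", C=C, max_iter=100000, random_state=seed
    )
    svm.fit(X_tr, y_tr)

    pred_tr, pred_te = svm.predict(X_tr), svm.predict(X_te)
    per_tr = _per_cluster_accuracy(y_tr, pred_tr).assign(partition="train")
    per_te = _per_cluster_accuracy(y_te, pred_te).assign(partition="test")
    return ClassifierBundle(
        coef=svm.coef_.copy(),
        intercept=svm.intercept_.copy(),
        classes=svm.classes_.copy(),
        stats=fm.stats,
        split_fraction=split,
        seed=seed,
        train_accuracy=float((pred_tr == y_tr).mean()),
        test_accuracy=float((pred_te == y_te).mean()),
        per_cluster_accuracy=pd.concat([per_tr, per_te], ignore_index=True),
    )


def predict_cluster(
    bundle: ClassifierBundle,
    params: pd.DataFrame,
    model: ClusterModel | None = None,
) -> pd.DataFrame:
    """Classify new cells from their raw motility parameters.

    Applies the bundle's stored normalization, predicts the cluster, and —
    when a ClusterModel with derived behavior classes is given — maps each
    cluster to its class.  Raises for non-positive parameters (they cannot
    be log-normalized).
    """
    fm = normalize_features(params, stats=bundle.stats)
    if fm.excluded:
        raise ValueError(
            f"{fm.excluded} cells have missing or non-positive parameters"
        )
    clusters = bundle.predict(fm.array())
    out = pd.DataFrame({"cluster": clusters}, index=fm.values.index)
    if model is not None:
        out["cluster_label"] = [model.cluster_label(c) for c in clusters]
        if model.class_map:
            out["behavior_class"] = model.classes_of(clusters)
    return out


def centroid_classify(
    model: ClusterModel, params: pd.DataFrame
) -> pd.DataFrame:
    """Nearest-centroid classification in normalized Euclidean space.

    Ties are broken toward the lowest cluster index (argmin convention).
    """
    fm = normalize_features(params, stats=model.stats)
    if fm.excluded:
        raise ValueError(
            f"{fm.excluded} cells have missing or non-positive parameters"
        )
    dist = np.linalg.norm(
        fm.array()[:, None, :] - model.centroids[None, :, :], axis=2
    )
    clusters = dist.argmin(axis=1)
    out = pd.DataFrame({"cluster": clusters}, index=fm.values.index)
    out["cluster_label"] = [model.cluster_label(c) for c in clusters]
    return out


def augmented_recluster_label(
    model: ClusterModel, training_values: np.ndarray, new_value: np.ndarray
) -> int:
    """Exact augmented-reclustering ground truth for one new cell.

    Re-runs Lloyd iterations on the training cells plus the new cell,
    warm-started from the fitted centroid directions, and returns the new
    cell's converged cluster (clusters keep their identity through the warm
    start because each converged direction moves only infinitesimally when
    a single cell is added to tens or hundreds of members).
    """
    Z = _row_standardize(np.vstack([training_values, new_value]))
    labels, _, _ = _lloyd_correlation(Z, model.directions.copy())
    return int(labels[-1])


def validate_on_simulated(
    bundle: ClassifierBundle,
    model: ClusterModel,
    cohort: TrajectorySet,
    exact: bool = False,
    training_values: np.ndarray | None = None,
) -> dict:
    """Score the SVM against augmented-reclustering ground truth.

    Fits the APRW parameters of every simulated cell, derives each cell's
    ground-truth cluster (frozen-objective assignment by default; exact
    one-cell-at-a-time re-clustering when ``exact=True``), and compares the
    SVM predictions.  Returns mean and per-cluster accuracy plus the count
    of unfittable cells.
    """
    table = fit_dataset(cohort)
    fm = normalize_features(table, stats=bundle.stats)
    unfittable = len(cohort) - len(fm)

    values = fm.array()
    if exact:
        if training_values is None:
            raise ValueError("exact mode needs the training feature matrix")
        truth = np.array(
            [
                augmented_recluster_label(model, training_values, v)
                for v in values
            ]
        )
    else:
        truth = assign_clusters(model, values)
    pred = bundle.predict(values)
    return {
        "mean_accuracy": float((pred == truth).mean()),
        "per_cluster": _per_cluster_accuracy(truth, pred),
        "n_scored": len(values),
        "n_unfittable": unfittable,
        "truth": truth,
        "predicted": pred,
        "index": fm.values.index,
    }
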