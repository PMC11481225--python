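"""Shannon-entropy quantification of motility heterogeneity.

Four plug-in entropies (natural logarithm, nats; 0 ln 0 = 0) characterize a
biological condition:

* spatial entropy  — over the fractional abundance of cells across the
  motility clusters (long-duration basis by default, short as a variant);
* state entropy    — over the four behavior-class frequencies at each stage
  (segments T1, T2, T3 and the long-duration stage C);
* transition entropy — over the 16 joint class pairs of a stage step
  (T1->T2, T2->T3, T3->C);
* conditional-transition entropy — over the class pairs of the two
  remaining stages, restricted to cells with a given class at a given stage.

A linear SVM over these condition-level entropies predicts whether a
condition was imaged in a 2D or a 3D microenvironment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from motilikit.temporal_dynamics import TransitionTable, transition_tables

_SUM_TOL = 1e-9
_MIN_COUNT = 5


def _shannon(p: np.ndarray) -> float:
    """Plug-in Shannon entropy in nats with the 0 ln 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -_SUM_TOL):
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"probabilities sum to {p.sum():.12f}, not 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _warn_sparse(counts: np.ndarray, what: str) -> None:
    counts = np.asarray(counts)
    if np.any((counts > 0) & (counts < _MIN_COUNT)):
        warnings.warn(
            f"{what}: some probabilities rest on fewer than {_MIN_COUNT} "
            "cells; the plug-in entropy estimate may be biased",
            stacklevel=3,
        )


def spatial_entropy(p) -> float:
    """Entropy of a condition's cluster-abundance vector (nats).

    Bounded by ln(number of clusters); 0 for a condition concentrated in a
    single cluster.
    """
    return _shannon(np.asarray(p, dtype=float))


def shannon_heterogeneity(p) -> float:
    """Per-condition heterogeneity: entropy over the short-duration
    cluster abundances (alias of :func:`spatial_entropy` on that basis)."""
    return spatial_entropy(p)


def state_entropy(records: pd.DataFrame) -> dict[str, float]:
    """Behavior-class entropy per stage (T1, T2, T3 from the short classes,
    C from the long classes), in nats; bounded by ln 4."""
    if records.empty:
        raise ValueError("no records")
    out = {}
    for stage in ("T1", "T2", "T3", "C"):
        counts = records[f"class_{stage}"].value_counts()
        _warn_sparse(counts.to_numpy(), f"state entropy at {stage}")
        out[stage] = _shannon(counts.to_numpy() / counts.sum())
    return out


def transition_entropy(table: TransitionTable) -> float:
    """Entropy of the joint class-pair distribution of one step (nats).

    Uniform over the 16 pairs gives ln 16; a deterministic identity
    transition from a uniform start gives ln 4.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"empty transition table for step {table.step}")
    _warn_sparse(counts, f"transition entropy {table.step}")
    return _shannon(counts.ravel() / counts.sum())


_CONDITIONING = {
    "T1": ("T2", "T3"),
    "T2": ("T1", "T3"),
    "T3": ("T1", "T2"),
}


def conditional_transition_entropy(
    records: pd.DataFrame, position: str, class_label: str
) -> float:
    """Entropy over the remaining two stages' class pairs, restricted to
    cells with ``class_label`` at ``position`` (one of T1, T2, T3).

    Returns NaN (reported missing) when the conditioning subset is empty.
    """
    if position not in _CONDITIONING:
        raise ValueError("position must be one of T1, T2, T3")
    a, b = _CONDITIONING[position]
    subset = records[records[f"class_{position}"] == class_label]
    if subset.empty:
        return np.nan
    counts = pd.crosstab(subset[f"class_{a}"], subset[f"class_{b}"])
    _warn_sparse(
        counts.to_numpy(),
        f"conditional transition entropy ({position}={class_label})",
    )
    arr = counts.to_numpy(dtype=float)
    return _shannon(arr.ravel() / arr.sum())


def entropy_report(
    records: pd.DataFrame,
    cluster_abundance: pd.DataFrame,
    short_abundance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-condition entropy profile.

    ``cluster_abundance`` holds per-condition abundance over the
    long-duration clusters (rows sum to 1); ``short_abundance`` optionally
    adds the short-cluster variant.  Transition records are grouped by
    condition for the state/transition/conditional entropies.  Conditions
    missing from either input yield NaNs for the affected columns.
    """
    conditions = sorted(
        set(cluster_abundance.index) | set(records["condition_id"])
    )
    rows = []
    for cond in conditions:
        row = {"condition_id": cond}
        if cond in cluster_abundance.index:
            row["S_spatial"] = spatial_entropy(
                cluster_abundance.loc[cond].to_numpy()
            )
        if short_abundance is not None and cond in short_abundance.index:
            row["S_spatial_short"] = spatial_entropy(
                short_abundance.loc[cond].to_numpy()
            )
        sub = records[records["condition_id"] == cond]
        if not sub.empty:
            for stage, value in state_entropy(sub).items():
                row[f"S_state_{stage}"] = value
            tables = transition_tables(sub)
            for step, table in tables.items():
                key = step.replace("->", "")
                row[f"S_transition_{key}"] = transition_entropy(table)
            short_classes = sorted(
                set(sub["class_T1"]) | set(sub["class_T2"])
                | set(sub["class_T3"])
            )
            for pos in ("T1", "T2", "T3"):
                for label in short_classes:
                    row[f"S_cond_{pos}_{label}"] = (
                        conditional_transition_entropy(sub, pos, label)
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition_id")


def predict_dimensionality(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_sets: dict[str, list[str]] | None = None,
    iterations: int = 25,
    split: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Linear-SVM prediction of 2D versus 3D from condition-level features.

    For every feature set (each entropy alone, their combination, or any
    caller-supplied grouping such as mean motility parameters), repeats
    ``iterations`` random ``split`` : 1-split partitions of the conditions,
    trains a linear SVM on the standardized features, and reports the mean
    test accuracy plus the ROC/AUC computed from the decision scores pooled
    over iterations.
    """
    y = pd.Series(labels).reindex(features.index)
    if y.isna().any():
        raise ValueError("every condition needs a 2D/3D label")
    y_bin = (y == "3D").astype(int).to_numpy()
    if len(np.unique(y_bin)) < 2:
        raise ValueError("need both 2D and 3D conditions")

    if feature_sets is None:
        feature_sets = {c: [c] for c in features.columns}
        feature_sets["combined"] = list(features.columns)

    rng = np.random.default_rng(seed)
    results, rocs = [], {}
    for name, cols in feature_sets.items():
        X = features[cols].to_numpy(dtype=float)
        keep = np.all(np.isfinite(X), axis=1)
        Xk, yk = X[keep], y_bin[keep]
        accs, pooled_scores, pooled_truth = [], [], []
        for _ in range(iterations):
            state = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                Xk, yk, train_size=split, stratify=yk, random_state=state
            )
            scaler = StandardScaler().fit(X_tr)
            svm = LinearSVC(C=1.0, max_iter=20000, random_state=state)
            svm.fit(scaler.transform(X_tr), y_tr)
            scores = svm.decision_function(scaler.transform(X_te))
            accs.append(float((svm.predict(scaler.transform(X_te)) == y_te).mean()))
            pooled_scores.append(scores)
            pooled_truth.append(y_te)
        pooled_scores = np.concatenate(pooled_scores)
        pooled_truth = np.concatenate(pooled_truth)
        fpr, tpr, _ = roc_curve(pooled_truth, pooled_scores)
        results.append(
            {
                "feature_set": name,
                "n_features": len(cols),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "auc": float(auc(fpr, tpr)),
            }
        )
        rocs[name] = (fpr, tpr)
    return pd.DataFrame(results).set_index("feature_set"), rocs
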