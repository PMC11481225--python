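"""Motility-state discovery: normalization, correlation-distance k-means,
behavior classes, coherence and abundance profiles.

Cells are represented by their eight motility parameters, natural-log
transformed and z-scored per column.  k-means runs on correlation distance
(1 - Pearson correlation between a cell's 8-vector and a centroid), which
groups cells by the *shape* of their parameter profile rather than its
magnitude.  Cluster centroids are then hierarchically clustered (average
linkage, correlation distance) and the dendrogram cut into four coarse
behavior classes, labeled in ascending order of mean MSD100 so that class 1
is the least and class 4 the most motile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from motilikit.aprw import PARAMETER_NAMES

_ID_COLS = ["condition_id", "cell_id"]


@dataclass
class NormalizationStats:
    """Per-column mean and sd of the log-transformed training parameters."""

    columns: list[str]
    log_mean: np.ndarray
    log_sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "log_mean": self.log_mean.tolist(),
            "log_sd": self.log_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            columns=list(d["columns"]),
            log_mean=np.asarray(d["log_mean"], dtype=float),
            log_sd=np.asarray(d["log_sd"], dtype=float),
        )


@dataclass
class FeatureMatrix:
    """Log/z-score normalized cells-by-parameters matrix.

    ``values`` keeps the identifying columns of the source table in its
    index; ``excluded`` counts cells dropped for NaN or non-positive
    parameters.
    """

    values: pd.DataFrame
    stats: NormalizationStats
    excluded: int = 0

    def __len__(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return self.values.to_numpy()

    def conditions(self) -> np.ndarray:
        return self.values.index.get_level_values("condition_id").to_numpy()


def normalize_features(
    params: pd.DataFrame, stats: NormalizationStats | None = None
) -> FeatureMatrix:
    """Natural-log transform then z-score the eight motility parameters.

    With ``stats`` supplied (scoring new cells against a trained model) the
    stored normalization is applied instead of refitting, so training and
    scoring live in the same feature space.  Cells with missing or
    non-positive parameters are excluded and counted.
    """
    cols = PARAMETER_NAMES
    missing = [c for c in cols if c not in params.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    data = params.copy()
    if all(c in data.columns for c in _ID_COLS):
        data = data.set_index(_ID_COLS)
    block = data[cols]
    valid = block.notna().all(axis=1) & (block > 0).all(axis=1)
    excluded = int((~valid).sum())
    logged = np.log(block.loc[valid].to_numpy(dtype=float))

    if stats is None:
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(
                f"cannot z-score degenerate columns (need >= 2 distinct "
                f"values): {bad}"
            )
        stats = NormalizationStats(list(cols), mean, sd)
    z = (logged - stats.log_mean) / stats.log_sd
    values = pd.DataFrame(z, index=block.loc[valid].index, columns=cols)
    return FeatureMatrix(values=values, stats=stats, excluded=excluded)


def denormalize(fm: FeatureMatrix) -> pd.DataFrame:
    """Invert the z-score and log transforms (round-trip check helper)."""
    raw = np.exp(fm.array() * fm.stats.log_sd + fm.stats.log_mean)
    return pd.DataFrame(raw, index=fm.values.index, columns=fm.stats.columns)


# ---------------------------------------------------------------------------
# correlation-distance k-means
# ---------------------------------------------------------------------------

def _row_standardize(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm (correlation geometry)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Xc / norms


def correlation_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows of a and rows of b."""
    return 1.0 - _row_standardize(np.atleast_2d(a)) @ _row_standardize(
        np.atleast_2d(b)
    ).T


@dataclass
class ClusterModel:
    """A fitted motility-cluster model.

    centroids : (k, 8) means of member cells in the normalized feature
        space (used for Euclidean coherence and nearest-centroid scoring).
    directions : (k, 8) row-standardized centroid directions (used for the
        correlation-distance assignment rule of the k-means objective).
    assignments : integer cluster per training cell, aligned with the
        training FeatureMatrix index.
    class_map : cluster index -> behavior-class label (set by
        :func:`derive_behavior_classes`).
    """

    k: int
    centroids: np.ndarray
    directions: np.ndarray
    assignments: pd.Series
    stats: NormalizationStats
    inertia: float
    seed: int
    prefix: str = "S"
    class_map: dict[int, str] = field(default_factory=dict)
    linkage: np.ndarray | None = None

    def cluster_label(self, idx) -> str:
        return f"{self.prefix}{int(idx) + 1}"

    @property
    def cluster_labels(self) -> list[str]:
        return [self.cluster_label(i) for i in range(self.k)]

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.class_map.values()))

    def classes_of(self, clusters: np.ndarray) -> np.ndarray:
        if not self.class_map:
            raise ValueError("behavior classes not derived yet")
        return np.array([self.class_map[int(c)] for c in clusters])

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "prefix": self.prefix,
            "seed": self.seed,
            "inertia": self.inertia,
            "centroids": self.centroids.tolist(),
            "directions": self.directions.tolist(),
            "stats": self.stats.to_dict(),
            "class_map": {str(k): v for k, v in self.class_map.items()},
            "linkage": None if self.linkage is None else self.linkage.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            k=int(d["k"]),
            centroids=np.asarray(d["centroids"], dtype=float),
            directions=np.asarray(d["directions"], dtype=float),
            assignments=pd.Series(dtype=int),
            stats=NormalizationStats.from_dict(d["stats"]),
            inertia=float(d["inertia"]),
            seed=int(d["seed"]),
            prefix=d["prefix"],
            class_map={int(k): v for k, v in d["class_map"].items()},
            linkage=None
            if d["linkage"] is None
            else np.asarray(d["linkage"], dtype=float),
        )


def _kmeanspp_init(
    Z: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding in correlation geometry; returns direction rows."""
    n = len(Z)
    idx = [int(rng.integers(n))]
    d2 = np.maximum(1.0 - Z @ Z[idx[-1]], 0.0) ** 2
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, np.maximum(1.0 - Z @ Z[idx[-1]], 0.0) ** 2)
    return Z[idx].copy()


def _lloyd_correlation(
    Z: np.ndarray, directions: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations under the correlation-distance objective.

    Assign each row to the direction of highest correlation; re-estimate
    each direction as the (renormalized) mean of its member rows.  Empty
    clusters are re-seeded from the currently worst-fit point.  The
    objective (total 1 - corr) is non-increasing across iterations.
    """
    k = len(directions)
    labels = None
    for _ in range(max_iter):
        sim = Z @ directions.T
        new_labels = sim.argmax(axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = Z[labels == j]
            if len(members) == 0:
                worst = int(np.argmin(sim.max(axis=1)))
                directions[j] = Z[worst]
                labels[worst] = j
                continue
            mean = members.mean(axis=0)  # zero-mean by linearity
            norm = np.linalg.norm(mean)
            if norm > 0:
                directions[j] = mean / norm
    inertia = float(np.sum(1.0 - (Z @ directions.T)[np.arange(len(Z)), labels]))
    return labels, directions, inertia


def kmeans_correlation(
    fm: FeatureMatrix,
    k: int,
    replicates: int = 50,
    seed: int = 0,
    prefix: str = "S",
) -> ClusterModel:
    """Correlation-distance k-means with seeded multi-start.

    The best of ``replicates`` k-means++-seeded runs (lowest total
    within-cluster correlation distance) is kept.  Cluster indices are
    relabeled in ascending order of the centroid MSD100 column so the
    numbering is reproducible across runs and row orderings.
    """
    X = fm.array()
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    Z = _row_standardize(X)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(replicates, 1)):
        init = _kmeanspp_init(Z, k, rng)
        labels, directions, inertia = _lloyd_correlation(Z, init)
        if best is None or inertia < best[2]:
            best = (labels, directions, inertia)
    labels, directions, inertia = best

    # canonical cluster order: ascending mean MSD100 (normalized scale)
    msd100_col = fm.stats.columns.index("MSD100")
    means = np.array(
        [X[labels == j, msd100_col].mean() for j in range(k)]
    )
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    directions = directions[order]
    centroids = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])

    return ClusterModel(
        k=k,
        centroids=centroids,
        directions=directions,
        assignments=pd.Series(labels, index=fm.values.index, name="cluster"),
        stats=fm.stats,
        inertia=inertia,
        seed=seed,
        prefix=prefix,
    )


def assign_clusters(model: ClusterModel, values: np.ndarray) -> np.ndarray:
    """Assign rows (normalized feature space) under the frozen k-means
    objective: highest correlation with a stored centroid direction."""
    Z = _row_standardize(np.atleast_2d(values))
    return (Z @ model.directions.T).argmax(axis=1)


def select_k(
    fm: FeatureMatrix,
    k_range,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Inertia and mean silhouette per candidate k.

    The elbow candidate (maximum second difference of the inertia curve) is
    annotated; the final choice of k remains with the user.
    """
    rows = []
    for k in k_range:
        model = kmeans_correlation(fm, k, replicates=replicates, seed=seed)
        sil = np.nan
        if 2 <= k < len(fm):
            sil = float(
                silhouette_score(
                    fm.array(), model.assignments.to_numpy(),
                    metric="correlation",
                )
            )
        rows.append({"k": k, "inertia": model.inertia, "silhouette": sil})
    out = pd.DataFrame(rows)
    out["elbow"] = False
    if len(out) >= 3:
        second_diff = np.diff(out["inertia"].to_numpy(), n=2)
        out.loc[out.index[1 + int(np.argmax(second_diff))], "elbow"] = True
    return out


def coherence_matrix(fm: FeatureMatrix, model: ClusterModel) -> pd.DataFrame:
    """Euclidean distance of every cell to every centroid (z-score space).

    Rows sorted by assigned cluster produce the staircase structure: small
    distances down the block diagonal, larger ones elsewhere.
    """
    dist = cdist(fm.array(), model.centroids)
    return pd.DataFrame(
        dist, index=fm.values.index, columns=model.cluster_labels
    )


def derive_behavior_classes(
    model: ClusterModel, n_classes: int = 4, class_prefix: str | None = None
) -> ClusterModel:
    """Group cluster centroids into coarse behavior classes.

    Average-linkage hierarchical clustering of the centroids on correlation
    distance, cut into ``n_classes``; classes are labeled (SG1..SG4 for
    short-duration models, CG1..CG4 for long) in ascending order of their
    member clusters' mean MSD100.
    """
    if n_classes > model.k:
        raise ValueError(f"n_classes={n_classes} exceeds k={model.k}")
    prefix = class_prefix or f"{model.prefix}G"
    link = hierarchy.linkage(
        model.centroids, method="average", metric="correlation"
    )
    raw = hierarchy.fcluster(link, t=n_classes, criterion="maxclust")
    msd100_col = model.stats.columns.index("MSD100")
    group_means = {
        g: model.centroids[raw == g, msd100_col].mean() for g in np.unique(raw)
    }
    ordered = sorted(group_means, key=group_means.get)
    rank = {g: i + 1 for i, g in enumerate(ordered)}
    model.class_map = {
        j: f"{prefix}{rank[raw[j]]}" for j in range(model.k)
    }
    model.linkage = link
    return model


def abundance_profiles(
    model: ClusterModel,
    assignments: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition fractional abundance over clusters and behavior classes.

    Returns ``(cluster_profiles, class_profiles)``; each row is a condition
    and sums to 1.  Pass ``assignments`` (a Series indexed by
    (condition_id, cell_id)) to profile cells other than the training set.
    """
    assign = model.assignments if assignments is None else assignments
    cond = assign.index.get_level_values("condition_id").to_numpy()
    counts = pd.crosstab(
        cond, assign.to_numpy(), rownames=["condition_id"],
        colnames=["cluster"],
    ).reindex(columns=range(model.k), fill_value=0)
    clusters = counts.div(counts.sum(axis=1), axis=0)
    clusters.columns = model.cluster_labels

    if model.class_map:
        ccounts = pd.crosstab(
            cond, model.classes_of(assign.to_numpy()),
            rownames=["condition_id"], colnames=["class"],
        ).reindex(columns=model.class_labels, fill_value=0)
        classes = ccounts.div(ccounts.sum(axis=1), axis=0)
    else:
        classes = pd.DataFrame(index=clusters.index)
    return clusters, classes


def embed_tsne(
    fm: FeatureMatrix, seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """Deterministic 2D t-SNE embedding of the normalized features."""
    if len(fm) <= 3 * perplexity:
        raise ValueError(
            f"n_cells={len(fm)} must exceed 3 x perplexity ({3 * perplexity})"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        init="pca",
    ).fit_transform(fm.array())
    return pd.DataFrame(
        coords, index=fm.values.index, columns=["tsne1", "tsne2"]
    )
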