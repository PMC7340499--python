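"""Cell-type clustering: supervised k-means and PCA on feature tables.

Two uses in the pipeline:

* morphological classification: k-means (k=2) on the (LRI, ORI) plane,
  where the 'complex' cluster is the one whose centre has the greater
  LRI + ORI sum (complex cells occupy the upper-right quadrant);
* physiological classification: z-score + PCA on the eight intrinsic
  properties, then k-means on the leading component scores.

Cluster-index semantics are always fixed *post hoc* by ordering the
centres (descending coordinate sum), never by initialisation, so labels
are stable across seeds up to data, and cluster 0 is the "high" group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "PcaResult",
    "kmeans",
    "elbow_wss",
    "zscore",
    "zscore_pca",
    "assign_new",
    "concordance",
]

PHYSIOLOGY_FEATURES = [
    "rmp_mV",
    "sag_index",
    "rin_MOhm",
    "spike_amplitude_mV",
    "adaptation_ratio",
    "f_2x_Hz",
    "spike_threshold_mV",
    "ahp_mV",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    centers: np.ndarray
    wss: float
    seed: int
    n_init: int
    row_ids: np.ndarray | None = None
    feature_names: list[str] | None = None

    def recompute_wss(self, X: np.ndarray) -> float:
        """Within-cluster sum of squares from labels and centres."""
        d = X - self.centers[self.labels]
        return float(np.sum(d * d))


def _as_matrix(features) -> tuple[np.ndarray, np.ndarray | None, list[str] | None]:
    if isinstance(features, pd.DataFrame):
        if features.isna().any().any():
            raise ValueError("feature matrix contains NaN; drop incomplete rows first")
        return features.to_numpy(dtype=float), features.index.to_numpy(), list(features.columns)
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN; drop incomplete rows first")
    return X, None, None


def _canonical_order(centers: np.ndarray) -> np.ndarray:
    """Cluster ordering: descending centre coordinate sum, so index 0 is the
    cluster with the greatest feature sum (e.g. 'complex' on LRI+ORI)."""
    sums = centers.sum(axis=1)
    return np.argsort(-sums, kind="stable")


def kmeans(features, k: int, seed: int = 0, n_init: int = 50) -> ClusterResult:
    """Lloyd's k-means with k-means++ init, best of ``n_init`` restarts.

    Deterministic for a fixed seed.  Labels are renumbered so that cluster
    indices follow the canonical centre ordering.
    """
    X, ids, names = _as_matrix(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    order = _canonical_order(km.cluster_centers_)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return ClusterResult(
        labels=remap[raw],
        centers=km.cluster_centers_[order],
        wss=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        row_ids=ids,
        feature_names=names,
    )


def elbow_wss(features, k_max: int, seed: int = 0, n_init: int = 20) -> list[tuple[int, float]]:
    """WSS versus k for the elbow diagnostic (k = 1..k_max).

    Non-increasing in k by construction: in addition to the restarts, each
    k is warm-started from the k-1 solution plus the point farthest from
    its assigned centre.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X, _, _ = _as_matrix(features)
    out: list[tuple[int, float]] = []
    prev_centers: np.ndarray | None = None
    for k in range(1, k_max + 1):
        best = kmeans(X, k, seed=seed, n_init=n_init)
        if prev_centers is not None and len(X) >= k:
            d = cdist(X, prev_centers).min(axis=1)
            init = np.vstack([prev_centers, X[int(np.argmax(d))]])
            warm = KMeans(n_clusters=k, init=init, n_init=1).fit(X)
            if warm.inertia_ < best.wss:
                order = _canonical_order(warm.cluster_centers_)
                remap = np.empty(k, dtype=int)
                remap[order] = np.arange(k)
                best = ClusterResult(
                    labels=remap[warm.labels_],
                    centers=warm.cluster_centers_[order],
                    wss=float(warm.inertia_),
                    seed=seed,
                    n_init=n_init,
                )
        out.append((k, best.wss))
        prev_centers = best.centers
    return out


def zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise standardisation; returns (z, means, sds)."""
    means = df.mean()
    sds = df.std(ddof=0)
    return (df - means) / sds, means, sds


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: np.ndarray              # (n_features, n_components)
    explained_variance_ratio: np.ndarray
    dropped_rows: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)
    means: pd.Series | None = None
    sds: pd.Series | None = None


def zscore_pca(df: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """z-score columns then project onto the leading principal components.

    Rows with any missing feature are dropped (and logged); zero-variance
    columns are removed before the decomposition.  Component sign is fixed
    by making each loading vector's largest-magnitude entry positive.
    """
    complete = df.dropna()
    dropped_rows = [i for i in df.index if i not in complete.index]
    if dropped_rows:
        logger.info("zscore_pca: dropped %d incomplete rows: %s", len(dropped_rows), dropped_rows)
    var = complete.var(ddof=0)
    dropped_cols = list(var.index[var == 0.0])
    if dropped_cols:
        logger.info("zscore_pca: removed zero-variance columns: %s", dropped_cols)
    work = complete.drop(columns=dropped_cols)
    z, means, sds = zscore(work)
    n_components = min(n_components, z.shape[1], len(z))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T.copy()          # (features, components)
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=complete.index, columns=[f"PC{j + 1}" for j in range(n_components)]
        ),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_rows=dropped_rows,
        dropped_columns=dropped_cols,
        means=means,
        sds=sds,
    )


def assign_new(points, reference: ClusterResult) -> np.ndarray:
    """Nearest-centre assignment of new cells in the reference feature space.

    Equidistant ties go to the lower cluster index.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] != reference.centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {P.shape[1]} features, "
            f"centers have {reference.centers.shape[1]}"
        )
    return np.argmin(cdist(P, reference.centers), axis=1)


@dataclass
class ConcordanceResult:
    table: pd.DataFrame                # contingency counts, a rows x b cols
    mapping: dict                      # cluster index in a -> matched index in b
    agreement: float


def concordance(labels_a, labels_b, ids_a=None, ids_b=None) -> ConcordanceResult:
    """Contingency table and majority-matched agreement of two labelings.

    When cell ids are given the label sets are joined on them; missing ids
    raise with the offending list.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if ids_a is not None or ids_b is not None:
        sa = pd.Series(a, index=ids_a)
        sb = pd.Series(b, index=ids_b)
        missing = sorted(set(sa.index) ^ set(sb.index))
        if missing:
            raise ValueError(f"cell ids not present in both label sets: {missing}")
        sb = sb.loc[sa.index]
        a, b = sa.to_numpy(), sb.to_numpy()
    elif len(a) != len(b):
        raise ValueError("label vectors differ in length and no ids were given")
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    rows, cols = list(table.index), list(table.columns)
    best_map, best_hits = {}, -1
    k = min(len(rows), len(cols))
    for perm in itertools.permutations(cols, k):
        hits = sum(table.loc[rows[i], perm[i]] for i in range(k))
        if hits > best_hits:
            best_hits = hits
            best_map = {rows[i]: perm[i] for i in range(k)}
    return ConcordanceResult(table=table, mapping=best_map, agreement=best_hits / len(a))
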