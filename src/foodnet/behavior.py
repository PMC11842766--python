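"""Behavioral food-similarity estimation and model-RDM construction.

From odd-one-out triplet responses, pairwise similarity of two items is the
proportion of triplets containing both in which neither was picked as the
odd one out.  PCA of the similarity matrix extracts the latent property
dimensions; silhouette-validated k-means on the first two components
recovers emergent food categories; Euclidean distances along single
components and ``1 - similarity`` provide the model RDMs used in RSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .rdm import RDM

__all__ = [
    "FoodSimilarityMatrix",
    "PCAResult",
    "triplet_similarity_matrix",
    "pca_similarity",
    "select_k_kmeans",
    "pc_rdm",
    "similarity_rdm",
]


@dataclass
class FoodSimilarityMatrix:
    """Item x item similarity in [0, 1] estimated from triplet proportions.

    ``n_pairs_observed[i, j]`` counts the triplets containing both i and j;
    a pair never observed has an undefined similarity, flagged by a zero
    count (its value is NaN).  The diagonal is fixed at 1: a self-pair can
    never contain its own odd item.
    """

    values: np.ndarray
    n_pairs_observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs_observed = np.asarray(self.n_pairs_observed, dtype=int)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def fully_observed(self) -> bool:
        off = ~np.eye(self.n_items, dtype=bool)
        return bool(np.all(self.n_pairs_observed[off] > 0))


def triplet_similarity_matrix(
    triplets: pd.DataFrame, n_items: int
) -> FoodSimilarityMatrix:
    """Estimate pairwise similarity from odd-one-out responses.

    ``S(i, j)`` is the proportion of triplets containing both i and j in
    which neither was the odd one out.  Item ids are 1-based; ``triplets``
    must have columns item_a, item_b, item_c, odd.
    """
    if len(triplets) == 0:
        raise ValueError("empty triplet list")
    trip = triplets[["item_a", "item_b", "item_c"]].to_numpy(dtype=int)
    odd = triplets["odd"].to_numpy(dtype=int)
    if trip.min() < 1 or trip.max() > n_items:
        raise ValueError("item id out of range 1..n_items")
    if not ((odd == trip[:, 0]) | (odd == trip[:, 1]) | (odd == trip[:, 2])).all():
        raise ValueError("odd item must be one of the triplet's items")
    if (
        (trip[:, 0] == trip[:, 1]) | (trip[:, 0] == trip[:, 2]) | (trip[:, 1] == trip[:, 2])
    ).any():
        raise ValueError("triplet items must be pairwise distinct")

    trip0 = trip - 1
    odd0 = odd - 1
    seen = np.zeros((n_items, n_items), dtype=int)
    kept = np.zeros((n_items, n_items), dtype=int)
    pair_idx = [(0, 1), (0, 2), (1, 2)]
    for a_col, b_col in pair_idx:
        i, j = trip0[:, a_col], trip0[:, b_col]
        np.add.at(seen, (i, j), 1)
        surv = (odd0 != i) & (odd0 != j)
        np.add.at(kept, (i, j), surv.astype(int))
    seen = seen + seen.T
    kept = kept + kept.T

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(seen > 0, kept / np.maximum(seen, 1), np.nan)
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(seen, 0)
    return FoodSimilarityMatrix(values=values, n_pairs_observed=seen)


@dataclass
class PCAResult:
    """Principal components of the similarity matrix (rows as observations)."""

    scores: np.ndarray  # (n_items, n_components)
    loadings: np.ndarray  # (n_items, n_components)
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_similarity(sim: FoodSimilarityMatrix) -> PCAResult:
    """Column-centered PCA of the similarity matrix.

    Rows of S are treated as observations and columns as variables; the
    columns are centered (no scaling to unit variance) and the components
    come from the eigendecomposition of the resulting covariance, computed
    via SVD.  ``variance_fraction`` holds the eigenvalue shares.
    """
    if not sim.fully_observed:
        raise ValueError("similarity matrix contains unobserved (flagged) pairs")
    x = sim.values - sim.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        imax = np.argmax(np.abs(vt[k]))
        if vt[k, imax] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(scores=scores, loadings=vt.T, variance_fraction=frac)


def select_k_kmeans(
    scores: np.ndarray,
    k_range: range = range(2, 11),
    n_init: int = 50,
    seed: int | None = 0,
) -> tuple[np.ndarray, dict[int, float], int]:
    """Silhouette-validated k-means over a range of cluster counts.

    For each k the best of ``n_init`` k-means initializations (by
    within-cluster sum of squares) is kept; the chosen k maximizes the
    mean silhouette coefficient under Euclidean distance on the scores.
    Returns ``(labels_for_chosen_k, silhouette_by_k, chosen_k)`` with
    1-based cluster labels.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k_range")
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range must lie within [2, n_items - 1]")

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(scores)
        if len(np.unique(labels)) < 2:
            raise ValueError(f"k-means degenerate at k={k} (duplicate points)")
        sil[k] = float(silhouette_score(scores, labels, metric="euclidean"))
        labels_by_k[k] = labels
    chosen = max(sil, key=lambda k: (sil[k], -k))
    return labels_by_k[chosen] + 1, sil, chosen


def pc_rdm(pca: PCAResult, component: int) -> RDM:
    """Euclidean-distance model RDM along one principal component.

    ``component`` is 1-based (component=1 is the first PC).  The RDM entry
    is ``|score_i - score_j|`` on that component, invariant to the
    component's sign.
    """
    if not 1 <= component <= pca.n_components:
        raise ValueError("component out of range")
    s = pca.scores[:, component - 1]
    d = np.abs(s[:, None] - s[None, :])
    labels = [f"food{i + 1:02d}" for i in range(len(s))]
    return RDM(labels=labels, d=d)


def similarity_rdm(sim: FoodSimilarityMatrix) -> RDM:
    """Model RDM ``1 - S`` from the behavioral similarity matrix."""
    if not sim.fully_observed:
        raise ValueError("similarity matrix contains unobserved (flagged) pairs")
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    labels = [f"food{i + 1:02d}" for i in range(sim.n_items)]
    return RDM(labels=labels, d=d)
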