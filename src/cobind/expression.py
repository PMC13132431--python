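"""Expression-profile normalization, PAM clustering, and complex intersection.

Differentially expressed genes are clustered on their relative expression
profiles across genotypes: raw counts are library-size scaled, transformed
with log2(x+1) as a variance-stabilizing stand-in, and centered per gene, so
each gene contributes only its response shape.  Clustering is partitioning
around medoids (k-medoids) with the deterministic BUILD initialization and
steepest-descent SWAP refinement; ``k`` can be fixed or selected by mean
silhouette over a range.  Cluster × complex-category intersections reuse the
exact pairwise multi-set test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances, silhouette_score
from sklearn.utils.validation import check_array

from .stats import fisher_2x2, pairwise_grid_tests

__all__ = [
    "PAM",
    "Clustering",
    "DegTargetResult",
    "normalize_counts",
    "pam_cluster",
    "cluster_profiles",
    "cluster_category_enrichment",
    "deg_target_association",
]


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size scale, log2(x+1) transform, and center each gene.

    Columns are scaled to the mean library depth, so doubling one sample's
    depth leaves its normalized column unchanged; after per-gene mean
    centering each row is a relative response profile.  All-zero gene rows
    are dropped with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    zero = X.sum(axis=1) == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero gene row(s)", stacklevel=2)
        counts = counts.loc[~zero]
        X = X[~zero]
    depth = X.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("a sample has zero total counts")
    scaled = X * (depth.mean() / depth)
    logged = np.log2(scaled + 1.0)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=counts.index, columns=counts.columns)


class PAM(BaseEstimator, ClusterMixin):
    """Partitioning around medoids (k-medoids), deterministic BUILD + SWAP.

    Parameters
    ----------
    n_clusters : int or "auto"
        Number of clusters; "auto" picks the k in ``k_range`` maximizing the
        mean silhouette width (ties go to the smaller k).
    k_range : tuple of int
        Inclusive (low, high) range searched when ``n_clusters="auto"``.
    metric : str
        Distance metric passed to :func:`sklearn.metrics.pairwise_distances`.
    max_iter : int
        Cap on SWAP sweeps; the objective is non-increasing so convergence
        is typically much earlier.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        0-based cluster index per sample.
    medoid_indices_ : ndarray of shape (n_clusters_,)
        Row indices of the medoids.
    n_clusters_ : int
        The number of clusters actually used.
    inertia_ : float
        Sum of distances of samples to their medoid.
    silhouette_ : float
        Mean silhouette width of the final clustering.
    """

    def __init__(
        self,
        n_clusters: int | str = "auto",
        k_range: tuple[int, int] = (2, 10),
        metric: str = "euclidean",
        max_iter: int = 100,
    ):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.metric = metric
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        n = X.shape[0]
        D = pairwise_distances(X, metric=self.metric)
        if self.n_clusters == "auto":
            lo, hi = self.k_range
            if lo < 2:
                raise ValueError("k_range must start at 2 or more")
            best = None
            for k in range(lo, min(hi, n - 1) + 1):
                medoids, labels, cost = _pam_fit(D, k, self.max_iter)
                sil = silhouette_score(D, labels, metric="precomputed")
                if best is None or sil > best[0]:
                    best = (sil, k, medoids, labels, cost)
            if best is None:
                raise ValueError("k_range empty after clipping to sample count")
            self.silhouette_, self.n_clusters_, self.medoid_indices_, self.labels_, self.inertia_ = best
        else:
            k = int(self.n_clusters)
            if not 2 <= k <= n:
                raise ValueError(f"n_clusters={k} invalid for {n} samples")
            medoids, labels, cost = _pam_fit(D, k, self.max_iter)
            self.medoid_indices_, self.labels_, self.inertia_ = medoids, labels, cost
            self.n_clusters_ = k
            self.silhouette_ = (
                silhouette_score(D, labels, metric="precomputed") if k < n else np.nan
            )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _pam_fit(D: np.ndarray, k: int, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    n = D.shape[0]
    # BUILD: start from the most central point, then greedily add the point
    # that most reduces the total distance to the nearest medoid.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        new = int(np.argmax(gain))
        medoids.append(new)
        dnear = np.minimum(dnear, D[new])
    medoids = np.array(sorted(medoids))

    # SWAP: steepest descent over all (medoid, candidate) exchanges.
    for _ in range(max_iter):
        Dm = D[medoids]  # (k, n)
        order = np.argsort(Dm, axis=0, kind="stable")
        nearest = order[0]  # index into medoids per point
        d1 = Dm[nearest, np.arange(n)]
        d2 = Dm[order[1], np.arange(n)]
        best_delta, best_swap = 0.0, None
        cand = np.setdiff1d(np.arange(n), medoids)
        Dc = D[cand]  # (n-k, n)
        cost = d1.sum()
        for mi in range(len(medoids)):
            mine = nearest == mi
            # points losing medoid mi fall back to their second-nearest or the
            # candidate; other points may only improve to the candidate
            new_cost = np.where(
                mine[None, :], np.minimum(Dc, d2[None, :]), np.minimum(Dc, d1[None, :])
            ).sum(axis=1)
            ci = int(np.argmin(new_cost))
            delta = new_cost[ci] - cost
            if delta < best_delta - 1e-12:
                best_delta, best_swap = delta, (mi, cand[ci])
        if best_swap is None:
            break
        mi, c = best_swap
        medoids[mi] = c
        medoids = np.array(sorted(medoids))
    Dm = D[medoids]
    labels = np.argmin(Dm, axis=0)
    cost = Dm[labels, np.arange(n)].sum()
    return medoids, labels.astype(np.int64), float(cost)


@dataclass
class Clustering:
    """Gene → cluster assignment with 1-based cluster ids."""

    labels: pd.Series  # gene -> cluster id 1..k
    medoids: list  # medoid gene id per cluster
    k: int
    silhouette: float


def pam_cluster(
    matrix: pd.DataFrame,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 10),
) -> Clustering:
    """Cluster normalized gene profiles (genes × samples) with PAM."""
    if isinstance(k, (int, np.integer)) and k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} genes available")
    est = PAM(n_clusters=k, k_range=k_range).fit(matrix.to_numpy())
    labels = pd.Series(est.labels_ + 1, index=matrix.index, name="cluster")
    medoids = [matrix.index[i] for i in est.medoid_indices_]
    return Clustering(labels, medoids, est.n_clusters_, float(est.silhouette_))


def cluster_profiles(
    matrix: pd.DataFrame,
    clustering: Clustering,
    genotype_map: Mapping[str, str],
) -> pd.DataFrame:
    """Mean normalized value per (cluster, genotype), averaging replicates."""
    genotypes = pd.Series(dict(genotype_map))
    missing = set(matrix.columns) - set(genotypes.index)
    if missing:
        raise ValueError(f"samples without genotype: {sorted(missing)}")
    empty = set(genotypes.unique()) - set(genotypes[list(matrix.columns)].unique())
    if empty:
        raise ValueError(f"genotype(s) with zero samples: {sorted(empty)}")
    sub = matrix.loc[clustering.labels.index]
    by_geno = sub.T.groupby(genotypes[list(sub.columns)].to_numpy()).mean().T
    return by_geno.groupby(clustering.labels).mean()


def cluster_category_enrichment(
    clustering: Clustering,
    genedb: pd.DataFrame,
    background: Iterable | None = None,
    restrict_trb_bound: bool = True,
    tiers: tuple[float, float, float] = (0.0005, 0.005, 0.05),
) -> pd.DataFrame:
    """Cluster × complex-category grid of exact pairwise intersection tests.

    One labeling is the expression cluster (background genes outside any
    cluster are labeled "not-DEG"); the other is the gene's complex
    category, with genes bound by no TRB paralog bucketed as "no-TRB" when
    ``restrict_trb_bound`` is set (the complex sets then contain TRB-bound
    genes only).  The background defaults to all genes of the database.
    """
    missing = set(clustering.labels.index) - set(genedb.index)
    if missing:
        raise ValueError(f"clustered gene(s) absent from gene database: {sorted(missing)[:3]}")
    bg = pd.Index(background) if background is not None else genedb.index
    if len(bg) == 0:
        raise ValueError("empty background")
    labels_a = clustering.labels.reindex(bg)
    labels_a = labels_a.where(labels_a.notna(), "not-DEG")
    labels_a = labels_a.map(lambda v: v if v == "not-DEG" else f"cluster{int(v)}")
    cats = genedb.loc[bg, "category"].copy()
    if restrict_trb_bound:
        cats = cats.where(genedb.loc[bg, "trb_combo"] != "none", "no-TRB")
    return pairwise_grid_tests(labels_a, cats, background=bg, tiers=tiers)


@dataclass
class DegTargetResult:
    """Association between differential expression and target-gene status."""

    table: np.ndarray  # [[DEG∩target, DEG\target], [target\DEG, neither]]
    odds_ratio: float
    p_value: float


def deg_target_association(
    deg_genes: Iterable,
    target_genes: Iterable,
    background: Iterable,
    or_estimator: str = "conditional",
) -> DegTargetResult:
    """Fisher 2×2 test of DEG status against binding-target status."""
    bg = frozenset(background)
    if not bg:
        raise ValueError("empty background")
    degs = frozenset(deg_genes) & bg
    targets = frozenset(target_genes) & bg
    a = len(degs & targets)
    b = len(degs - targets)
    c = len(targets - degs)
    d = len(bg) - a - b - c
    table = np.array([[a, b], [c, d]])
    oddsratio, p = fisher_2x2(table, or_estimator=or_estimator)
    return DegTargetResult(table, oddsratio, p)
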