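"""Covariate clustering of DHSs into background-rate groups.

DHSs are binned per chromosome by k-means on the five z-normalized
covariates.  Every final cluster must hold at least ``min_members`` DHSs and
at least ``min_length`` bp of total masked length; undersized clusters are
greedily merged into the valid cluster with the nearest centroid (ties
broken by lower cluster id).  Cluster granularity defaults to the cohort
scale of roughly one cluster per 1,500 DHSs, apportioned to chromosomes
proportionally to their DHS counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = ["CovariateKMeans", "cluster_dhs", "summarize_clusters"]


class CovariateKMeans(BaseEstimator, ClusterMixin):
    """Per-chromosome k-means with minimum cluster-size constraints.

    Parameters
    ----------
    n_clusters : int
        Cohort-level cluster target; per-chromosome k is
        ``max(1, round(n_chrom / n_total * n_clusters))``.
    min_members : int, default 100
        Minimum DHSs per final cluster.
    min_length : int, default 20000
        Minimum total masked length (bp) per final cluster.
    per_chromosome : bool, default True
        Cluster each chromosome independently (cluster ids remain globally
        unique).
    n_init : int, default 10
        k-means restarts.
    random_state : int or None
        Seed; identical inputs and seed give identical assignments.

    Attributes
    ----------
    labels_ : ndarray of global cluster ids, one per DHS.
    cluster_centers_ : dict cluster id -> centroid in covariate space.
    """

    def __init__(
        self,
        n_clusters: int = 223,
        min_members: int = 100,
        min_length: int = 20_000,
        per_chromosome: bool = True,
        n_init: int = 10,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.min_members = min_members
        self.min_length = min_length
        self.per_chromosome = per_chromosome
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None, *, chrom=None, lengths=None) -> "CovariateKMeans":
        """Cluster the covariate matrix.

        Parameters
        ----------
        X : (n_dhs, n_covariates) array of normalized covariates.
        chrom : per-DHS chromosome labels; required if ``per_chromosome``.
        lengths : per-DHS masked lengths (bp) for the min-length constraint;
            if omitted the length constraint is waived.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if lengths is None:
            lengths = np.zeros(n)
            min_length = 0
        else:
            lengths = np.asarray(lengths, dtype=float)
            min_length = self.min_length
        labels = np.full(n, -1, dtype=int)
        centers: dict[int, np.ndarray] = {}
        next_id = 0
        if self.per_chromosome:
            if chrom is None:
                raise ValueError("per_chromosome=True requires chrom labels")
            chrom = np.asarray(chrom)
            groups = [(c, np.flatnonzero(chrom == c)) for c in sorted(set(chrom))]
        else:
            groups = [("all", np.arange(n))]
        for cname, idx in groups:
            k = max(1, round(len(idx) / n * self.n_clusters))
            if len(idx) < self.min_members:
                logger.warning(
                    "chromosome %s has %d DHSs (< %d); single cluster",
                    cname, len(idx), self.min_members,
                )
                k = 1
            k = min(k, len(idx))
            sub_labels, sub_centers = _constrained_kmeans(
                X[idx], lengths[idx], k, self.min_members, min_length,
                self.n_init, self.random_state,
            )
            for local_id, center in sub_centers.items():
                centers[next_id + local_id] = center
            labels[idx] = sub_labels + next_id
            next_id += max(sub_centers) + 1 if sub_centers else 0
        # compact ids to 0..K-1
        used = np.unique(labels)
        remap = {old: new for new, old in enumerate(used)}
        self.labels_ = np.array([remap[l] for l in labels])
        self.cluster_centers_ = {remap[old]: c for old, c in centers.items() if old in remap}
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_

    @property
    def n_clusters_(self) -> int:
        check_is_fitted(self, "labels_")
        return len(np.unique(self.labels_))


def _constrained_kmeans(X, lengths, k, min_members, min_length, n_init, random_state):
    """k-means followed by greedy merge of constraint-violating clusters."""
    km = KMeans(n_clusters=k, n_init=n_init, random_state=random_state)
    labels = km.fit_predict(X)
    centers = {i: km.cluster_centers_[i].copy() for i in range(k)}

    def stats(lbls):
        sizes = {i: int((lbls == i).sum()) for i in centers}
        lens = {i: float(lengths[lbls == i].sum()) for i in centers}
        return sizes, lens

    while len(centers) > 1:
        sizes, lens = stats(labels)
        invalid = [
            i for i in centers
            if sizes[i] < min_members or lens[i] < min_length
        ]
        if not invalid:
            break
        # merge the smallest invalid cluster into the nearest valid cluster
        # (nearest of any if no cluster is valid yet)
        src = min(invalid, key=lambda i: (sizes[i], i))
        valid = [i for i in centers if i != src and i not in invalid]
        others = valid if valid else [i for i in centers if i != src]
        dists = [(float(np.linalg.norm(centers[src] - centers[j])), j) for j in others]
        dists.sort()  # ties broken by lower cluster id
        dst = dists[0][1]
        members = (labels == src) | (labels == dst)
        labels[labels == src] = dst
        centers[dst] = X[members].mean(axis=0)
        del centers[src]
    # relabel to consecutive local ids (sorted by old id for determinism)
    old_ids = sorted(centers)
    remap = {old: new for new, old in enumerate(old_ids)}
    labels = np.array([remap[l] for l in labels])
    centers = {remap[old]: c for old, c in centers.items()}
    return labels, centers


def cluster_dhs(
    vectors: pd.DataFrame,
    chrom: np.ndarray,
    lengths: np.ndarray | None = None,
    n_clusters: int = 223,
    per_chromosome: bool = True,
    seed: int | None = None,
) -> np.ndarray:
    """Functional wrapper over :class:`CovariateKMeans`; returns labels."""
    est = CovariateKMeans(
        n_clusters=n_clusters, per_chromosome=per_chromosome, random_state=seed
    )
    return est.fit_predict(vectors.to_numpy(), chrom=chrom, lengths=lengths)


def summarize_clusters(
    labels: np.ndarray, lengths: np.ndarray, counts: np.ndarray
) -> pd.DataFrame:
    """Per-cluster member count, total masked length and mutation count."""
    df = pd.DataFrame({"cluster": labels, "L": lengths, "n": counts})
    out = df.groupby("cluster").agg(
        members=("L", "size"), total_length=("L", "sum"), total_mutations=("n", "sum")
    )
    return out.reset_index()
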