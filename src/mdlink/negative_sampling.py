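"""Cluster-balanced selection of reliable negative training pairs.

Unobserved (zero) entries of the association matrix are unlabelled: most are
true negatives but some are undiscovered positives.  Drawing training
negatives uniformly risks concentrating them in dense regions of feature
space; clustering the candidate pool first and drawing equally from each
cluster spreads the negatives across the feature space instead.  Five
strategies are provided: plain random, KMeans, Gaussian mixture, spectral
co-clustering and spectral bi-clustering (row labels of the candidate
feature matrix in the latter two).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, SpectralBiclustering, SpectralCoclustering
from sklearn.mixture import GaussianMixture

from .core_data import AssociationNetwork

__all__ = ["NegativeSamplingPlan", "STRATEGIES", "candidate_negatives", "sample_negatives"]

STRATEGIES = ("random", "kmeans", "gaussian_mixture", "spectral_cocluster", "spectral_bicluster")


@dataclass(frozen=True)
class NegativeSamplingPlan:
    """How to pick negatives: strategy, cluster count (default 23), per-cluster quota, seed."""

    strategy: str = "kmeans"
    n_clusters: int = 23
    per_cluster: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.per_cluster != "auto" and int(self.per_cluster) < 1:
            raise ValueError("per_cluster must be >= 1 or 'auto'")


def candidate_negatives(net: AssociationNetwork) -> list[tuple[int, int]]:
    """All zero entries of Y as (microbe index, disease index), row-major."""
    return [tuple(p) for p in np.argwhere(net.Y == 0)]


def _cluster_labels(
    features: np.ndarray, plan: NegativeSamplingPlan
) -> np.ndarray:
    seed = plan.seed % (2**31)
    if plan.strategy == "kmeans":
        return KMeans(
            n_clusters=plan.n_clusters, random_state=seed, n_init=10
        ).fit_predict(features)
    if plan.strategy == "gaussian_mixture":
        return GaussianMixture(
            n_components=plan.n_clusters, random_state=seed
        ).fit_predict(features)
    if plan.strategy == "spectral_cocluster":
        model = SpectralCoclustering(n_clusters=plan.n_clusters, random_state=seed)
    elif plan.strategy == "spectral_bicluster":
        model = SpectralBiclustering(n_clusters=plan.n_clusters, random_state=seed)
    else:  # pragma: no cover
        raise ValueError(plan.strategy)
    # spectral co/bi-clustering require strictly positive matrices
    model.fit(np.asarray(features, dtype=float) + 1e-9)
    return model.row_labels_


def sample_negatives(
    features: np.ndarray,
    candidates: list[tuple[int, int]],
    plan: NegativeSamplingPlan,
    n_total: int,
) -> list[tuple[int, int]]:
    """Select ``n_total`` negative pairs from the candidate pool.

    strategy="random" draws uniformly without replacement.  Clustering
    strategies fit ``n_clusters`` clusters on the candidate feature rows and
    draw ``per_cluster`` (default ceil(n_total / n_clusters)) members from
    each non-empty cluster without replacement; small clusters contribute
    everything they have.  The union is truncated (or topped up from the
    remaining pool) uniformly at random to exactly ``n_total``.
    Deterministic given ``plan.seed``.
    """
    n_cand = len(candidates)
    if features is not None and len(features) != n_cand:
        raise ValueError("features row count must equal candidate count")
    if n_total > n_cand:
        raise ValueError(f"requested {n_total} negatives but only {n_cand} candidates")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rng = np.random.default_rng(plan.seed)

    if plan.strategy == "random":
        idx = rng.choice(n_cand, size=n_total, replace=False)
        return [candidates[i] for i in sorted(idx)]

    if plan.n_clusters > n_cand:
        raise ValueError(f"n_clusters={plan.n_clusters} exceeds candidate count {n_cand}")
    labels = _cluster_labels(np.asarray(features, dtype=float), plan)

    per = (
        math.ceil(n_total / plan.n_clusters)
        if plan.per_cluster == "auto"
        else int(plan.per_cluster)
    )
    chosen: list[int] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        take = min(per, members.size)
        chosen.extend(rng.choice(members, size=take, replace=False))

    if len(chosen) > n_total:
        chosen = list(rng.choice(chosen, size=n_total, replace=False))
    elif len(chosen) < n_total:
        rest = np.setdiff1d(np.arange(n_cand), chosen)
        top_up = rng.choice(rest, size=n_total - len(chosen), replace=False)
        chosen.extend(top_up)
    return [candidates[i] for i in sorted(chosen)]
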