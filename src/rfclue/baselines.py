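"""Averaged-proximity baseline (RFclust).

Instead of clustering each forest's proximity separately and combining
partitions, RFclust averages the proximity matrices of several
independent unsupervised forests, converts the average to a
dissimilarity sqrt(1 - S̄), and applies the same Ward agglomeration used
by the consensus stage. It is the natural head-to-head comparator for
the cluster-ensemble approach: same forests, consensus at the proximity
level rather than the partition level.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import Partition
from .errors import ValidationError
from .forest import ForestConfig, _as_matrix, build_unsupervised_forest, compute_proximity

__all__ = ["average_proximity", "rfclust", "AveragedProximityClustering"]


def average_proximity(g, n_forests: int, forest_cfg: ForestConfig, seed: int) -> np.ndarray:
    """Mean proximity over ``n_forests`` independent forests.

    Each forest gets a fresh synthetic class and an independent seed
    split from ``seed``.
    """
    if n_forests < 1:
        raise ValidationError("n_forests must be >= 1")
    X = _as_matrix(g)
    children = np.random.SeedSequence(seed).spawn(n_forests)
    total = np.zeros((X.shape[0], X.shape[0]))
    for child in children:
        cfg = ForestConfig(
            forest_cfg.ntrees,
            forest_cfg.max_leaf_nodes,
            forest_cfg.mtry,
            forest_cfg.n_synth,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        forest = build_unsupervised_forest(X, cfg)
        total += compute_proximity(forest, X)
    return total / n_forests


def rfclust(
    g,
    n_forests: int,
    forest_cfg: ForestConfig,
    k_final: int,
    seed: int = 0,
    distance: str = "sqrt-one-minus",
) -> Partition:
    """Ward-cut the averaged proximity into ``k_final`` clusters."""
    model = AveragedProximityClustering(
        n_clusters=k_final,
        n_forests=n_forests,
        ntrees=forest_cfg.ntrees,
        max_leaf_nodes=forest_cfg.max_leaf_nodes,
        mtry=forest_cfg.mtry,
        n_synth=forest_cfg.n_synth,
        distance=distance,
        random_state=seed,
    )
    model.fit(_as_matrix(g))
    return Partition(model.labels_ + 1)


class AveragedProximityClustering(ClusterMixin, BaseEstimator):
    """RFclust: Ward clustering of forest proximities averaged over runs.

    Parameters mirror :class:`~rfclue.consensus.RFClusterEnsemble` where
    they overlap; ``n_forests`` plays the role of the ensemble size.
    ``distance`` selects the proximity-to-distance transform
    ("sqrt-one-minus", the same sqrt(1-s) used by the base clustering,
    or "one-minus").

    Attributes
    ----------
    labels_ : (N,) 0-based cluster labels.
    mean_proximity_ : (N, N) averaged proximity matrix.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_forests: int = 10,
        ntrees: int = 500,
        max_leaf_nodes: int | None = None,
        mtry: int | None = None,
        n_synth: int | None = None,
        distance: str = "sqrt-one-minus",
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_forests = n_forests
        self.ntrees = ntrees
        self.max_leaf_nodes = max_leaf_nodes
        self.mtry = mtry
        self.n_synth = n_synth
        self.distance = distance
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.distance not in ("one-minus", "sqrt-one-minus"):
            raise ValidationError("distance must be 'one-minus' or 'sqrt-one-minus'")
        cfg = ForestConfig(
            ntrees=self.ntrees,
            max_leaf_nodes=self.max_leaf_nodes,
            mtry=self.mtry,
            n_synth=self.n_synth,
        )
        s_bar = average_proximity(X, self.n_forests, cfg, seed=self.random_state)
        self.mean_proximity_ = s_bar
        dist = 1.0 - s_bar
        if self.distance == "sqrt-one-minus":
            dist = np.sqrt(np.clip(dist, 0.0, None))
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="ward")
        raw = fcluster(z, t=self.n_clusters, criterion="maxclust")
        _, compact = np.unique(raw, return_inverse=True)
        self.labels_ = compact
        return self
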