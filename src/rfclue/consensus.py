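"""Consensus function: co-association matrix + Ward agglomeration.

The ensemble's M partitions are summarized by the co-association matrix
CO[i,j] = fraction of members placing i and j in the same cluster, a
similarity in [0,1] with unit diagonal whose entries are exact multiples
of 1/M. The final partition P* is obtained by Ward's minimum-variance
agglomerative clustering of the distance 1 - CO (optionally
sqrt(1 - CO)), cut at the requested number of clusters. Ward is computed
with the Lance–Williams recursion on the given distances treated as
Euclidean (the squared-distance "D2" dialect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import Partition, as_labels
from .ensemble import Ensemble, EnsembleConfig, KScheme, build_ensemble
from .errors import ValidationError
from .forest import ForestConfig, _as_matrix

__all__ = [
    "co_association",
    "consensus_partition",
    "run_rfclue",
    "RFcluEResult",
    "RFClusterEnsemble",
]

_CO_DISTANCES = ("one-minus", "sqrt-one-minus")


def co_association(e: Ensemble | list) -> np.ndarray:
    """CO[i,j] = |{m : member m co-clusters i and j}| / M."""
    members = e.partitions if isinstance(e, Ensemble) else list(e)
    if not members:
        raise ValidationError("empty ensemble")
    labels = [as_labels(p) for p in members]
    n = len(labels[0])
    counts = np.zeros((n, n), dtype=np.int64)
    for lab in labels:
        if len(lab) != n:
            raise ValidationError("ensemble members cover different individuals")
        counts += lab[:, None] == lab[None, :]
    return counts / float(len(labels))


def consensus_partition(
    co: np.ndarray, k_final: int, co_distance: str = "one-minus"
) -> Partition:
    """Ward-cut the co-association matrix into ``k_final`` clusters."""
    co = np.asarray(co, dtype=float)
    n = co.shape[0]
    if co.shape != (n, n):
        raise ValidationError("co-association matrix must be square")
    if not 1 <= k_final <= n:
        raise ValidationError(f"k_final={k_final} must be in [1, N={n}]")
    if co_distance not in _CO_DISTANCES:
        raise ValidationError(f"co_distance must be one of {_CO_DISTANCES}")
    dist = 1.0 - co
    if co_distance == "sqrt-one-minus":
        dist = np.sqrt(np.clip(dist, 0.0, None))
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    raw = fcluster(z, t=k_final, criterion="maxclust")
    _, compact = np.unique(raw, return_inverse=True)
    return Partition(compact + 1)


@dataclass
class RFcluEResult:
    """End-to-end outputs: consensus partition, CO matrix, raw ensemble."""

    partition: Partition
    coassociation: np.ndarray
    ensemble: Ensemble


def run_rfclue(
    g, cfg: EnsembleConfig, k_final: int, co_distance: str = "one-minus", n_jobs: int = 1
) -> RFcluEResult:
    """Build the ensemble, summarize it, and extract the final partition."""
    ens = build_ensemble(g, cfg, n_jobs=n_jobs)
    co = co_association(ens)
    p_star = consensus_partition(co, k_final, co_distance=co_distance)
    return RFcluEResult(p_star, co, ens)


class RFClusterEnsemble(ClusterMixin, BaseEstimator):
    """Random-forest cluster ensemble for population structure inference.

    Runs unsupervised RF clustering ``n_members`` times, accumulates the
    co-association matrix, and Ward-cuts it into ``n_clusters`` groups.

    Parameters
    ----------
    n_clusters : final number of clusters (the known K when evaluating
        against truth labels).
    n_members : ensemble size M.
    ntrees, max_leaf_nodes, mtry, n_synth : forest settings per member
        (defaults: MN = ceil(sqrt(N)), mtry = floor(sqrt(l)), n_synth = N).
    k_scheme : {"FixedK", "TrueK", "RandomK"} — per-member cluster count:
        ceil(sqrt(N)), ``true_k``, or uniform in [2, ceil(sqrt(N))].
    true_k : required when ``k_scheme="TrueK"``.
    co_distance : {"one-minus", "sqrt-one-minus"} transform before Ward.
    n_jobs : parallel member runs; results are identical for any value.
    random_state : master seed; the whole fit is deterministic given it.

    Attributes
    ----------
    labels_ : (N,) 0-based consensus labels.
    coassociation_ : (N, N) co-clustering fractions.
    ensemble_ : the :class:`~rfclue.ensemble.Ensemble` of member partitions.
    member_ks_ : the k drawn by each member.

    Examples
    --------
    >>> from rfclue import RFClusterEnsemble, SimulationConfig, simulate_populations
    >>> g, truth = simulate_populations(SimulationConfig(3, 20, 200, fst=0.3, seed=1))
    >>> model = RFClusterEnsemble(n_clusters=3, n_members=5, ntrees=100, random_state=1)
    >>> labels = model.fit_predict(g.values)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_members: int = 10,
        ntrees: int = 500,
        max_leaf_nodes: int | None = None,
        mtry: int | None = None,
        n_synth: int | None = None,
        k_scheme: str = "FixedK",
        true_k: int | None = None,
        co_distance: str = "one-minus",
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_members = n_members
        self.ntrees = ntrees
        self.max_leaf_nodes = max_leaf_nodes
        self.mtry = mtry
        self.n_synth = n_synth
        self.k_scheme = k_scheme
        self.true_k = true_k
        self.co_distance = co_distance
        self.n_jobs = n_jobs
        self.random_state = random_state

    def _config(self) -> EnsembleConfig:
        return EnsembleConfig(
            forest=ForestConfig(
                ntrees=self.ntrees,
                max_leaf_nodes=self.max_leaf_nodes,
                mtry=self.mtry,
                n_synth=self.n_synth,
            ),
            m=self.n_members,
            scheme=KScheme(self.k_scheme, true_k=self.true_k),
            master_seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = _as_matrix(X)
        result = run_rfclue(
            X,
            self._config(),
            k_final=self.n_clusters,
            co_distance=self.co_distance,
            n_jobs=self.n_jobs,
        )
        self.labels_ = result.partition.assignment - 1
        self.coassociation_ = result.coassociation
        self.ensemble_ = result.ensemble
        self.member_ks_ = list(result.ensemble.member_ks)
        return self
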