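"""Unsupervised random-forest clustering of genotype matrices.

A forest is trained to separate the observed individuals (class 0) from
a synthetic class (class 1) drawn from the product of the observed
per-marker marginals. Any dependence structure among markers — the
allele-frequency correlations that population structure induces — makes
the two classes separable, so the forest's leaves group similar
individuals. The proximity S[i,j] is the fraction of trees in which i
and j share a leaf; the dissimilarity D = sqrt(1 - S) is embedded into
Euclidean space by classical multidimensional scaling, and K-means on
the embedding yields one partition.

Tree engine: scikit-learn's RandomForestClassifier, which grows trees
best-first under a hard ``max_leaf_nodes`` cap with Gini splitting,
bootstrap resampling of the combined training set (sample size equal to
the training size, classical bagging) and per-node random feature
subsets of size ``mtry``; ``apply`` exposes per-sample leaf indices.
The standalone Gini helpers below document the split criterion and feed
the property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .datatypes import GenotypeMatrix, Partition
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ForestConfig",
    "Forest",
    "Embedding",
    "gini_impurity",
    "gini_gain",
    "generate_synthetic_class",
    "build_unsupervised_forest",
    "compute_proximity",
    "proximity_to_dissimilarity",
    "classical_mds",
    "kmeans_partition",
    "rf_cluster_once",
    "RandomForestClustering",
]


# ---------------------------------------------------------------------------
# Split criterion


def gini_impurity(class_counts) -> float:
    """Gini index of a node: sum_c p_c (1 - p_c), zero iff the node is pure."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValidationError("class counts must be a 1-D non-negative vector")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot score an empty node")
    p = counts / total
    return float((p * (1.0 - p)).sum())


def gini_gain(parent, left, right) -> float:
    """Impurity decrease of a binary split; always >= 0 by concavity.

    A non-splitting split (one empty child) contributes no weighted child
    impurity on the empty side and has zero gain.
    """
    parent = np.asarray(parent, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValidationError("left + right must equal parent counts")
    n = parent.sum()
    child_term = 0.0
    for child in (left, right):
        c = child.sum()
        if c > 0:
            child_term += (c / n) * gini_impurity(child)
    return float(gini_impurity(parent) - child_term)


# ---------------------------------------------------------------------------
# Synthetic class and forest


def _as_matrix(g) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        return g.values
    return np.asarray(g)


def generate_synthetic_class(g, n_synth: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n_synth rows from the product of g's per-marker marginals.

    Each synthetic marker value is drawn independently (with replacement)
    from the empirical values of that marker, so marginal distributions
    are preserved while any between-marker dependence is destroyed.
    """
    if n_synth < 1:
        raise ValidationError("n_synth must be >= 1")
    X = _as_matrix(g)
    out = np.empty((n_synth, X.shape[1]), dtype=X.dtype)
    for j in range(X.shape[1]):
        out[:, j] = rng.choice(X[:, j], size=n_synth, replace=True)
    return out


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    ``max_leaf_nodes`` (MN) defaults to ceil(sqrt(N)) of the data it is
    fitted on; ``mtry`` defaults to floor(sqrt(l)). ``n_synth`` defaults
    to N so the two-class problem is balanced.
    """

    ntrees: int = 500
    max_leaf_nodes: int | None = None
    mtry: int | None = None
    n_synth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntrees < 1:
            raise ValidationError("ntrees must be >= 1")
        if self.max_leaf_nodes is not None and self.max_leaf_nodes < 2:
            raise ValidationError("max_leaf_nodes must be >= 2")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")

    def resolved(self, n: int, l: int) -> "ForestConfig":
        mn = self.max_leaf_nodes or math.ceil(math.sqrt(n))
        mtry = self.mtry or max(1, math.floor(math.sqrt(l)))
        if mtry > l:
            raise ValidationError(f"mtry={mtry} exceeds number of markers l={l}")
        return ForestConfig(self.ntrees, mn, mtry, self.n_synth or n, self.seed)


@dataclass
class Forest:
    """A fitted unsupervised forest plus its training metadata."""

    model: RandomForestClassifier
    config: ForestConfig

    @property
    def ntrees(self) -> int:
        return self.config.ntrees

    def apply(self, X) -> np.ndarray:
        """Leaf index of each row of X in each tree; shape (n, ntrees)."""
        return self.model.apply(np.asarray(_as_matrix(X), dtype=np.float32))

    @property
    def oob_error(self) -> float:
        """Out-of-bag error of the original-vs-synthetic classification."""
        return 1.0 - float(self.model.oob_score_)


def build_unsupervised_forest(g, cfg: ForestConfig) -> Forest:
    """Grow a forest separating g from its marginal-resampled synthetic class."""
    X = _as_matrix(g)
    n, l = X.shape
    cfg = cfg.resolved(n, l)
    ss = np.random.SeedSequence(cfg.seed)
    synth_rng = np.random.default_rng(ss.spawn(1)[0])
    synth = generate_synthetic_class(X, cfg.n_synth, synth_rng)
    X_train = np.vstack([X, synth]).astype(np.float32)
    y_train = np.concatenate([np.zeros(n), np.ones(len(synth))])
    model = RandomForestClassifier(
        n_estimators=cfg.ntrees,
        criterion="gini",
        max_leaf_nodes=cfg.max_leaf_nodes,
        max_features=cfg.mtry,
        bootstrap=True,
        # below ~25 trees some rows are never out of bag and the score
        # is undefined for them
        oob_score=cfg.ntrees >= 25,
        random_state=int(ss.generate_state(1)[0] % (2**31)),
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    return Forest(model, cfg)


def compute_proximity(forest: Forest, g) -> np.ndarray:
    """S[i,j] = fraction of trees where individuals i and j share a leaf.

    All original individuals are passed down every tree (no out-of-bag
    restriction); entries are exact multiples of 1/ntrees with unit
    diagonal.
    """
    leaves = forest.apply(g)  # (N, ntrees)
    n, ntrees = leaves.shape
    same = leaves[:, None, :] == leaves[None, :, :]
    counts = same.sum(axis=2)
    return counts / float(ntrees)


def proximity_to_dissimilarity(s: np.ndarray) -> np.ndarray:
    """D = sqrt(1 - S), with an exactly zero diagonal."""
    s = np.asarray(s, dtype=float)
    d = np.sqrt(np.clip(1.0 - s, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Classical scaling + K-means


@dataclass
class Embedding:
    """Classical-scaling coordinates with the retained spectrum."""

    coordinates: np.ndarray  # (N, p)
    eigenvalues: np.ndarray  # (p,) positive, descending

    @property
    def p(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(d: np.ndarray, eig_tol: float | None = None) -> Embedding:
    """Embed a dissimilarity matrix into the smallest adequate Euclidean space.

    Double-centers -1/2 J D^2 J, eigendecomposes, and keeps eigenvalues
    above ``eig_tol`` (default: max(N * eps * lambda_max, 1e-10), a
    relative guard against numerical noise). Coordinates are eigenvectors
    scaled by sqrt(eigenvalue); the retained dimension p is the embedding
    dimension.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValidationError("dissimilarity must be a symmetric square matrix")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("dissimilarity diagonal must be zero")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eig_tol is None:
        eig_tol = max(n * np.finfo(float).eps * max(eigval[0], 0.0), 1e-10)
    keep = eigval > eig_tol
    if not keep.any():
        raise DegenerateInputError(
            "degenerate dissimilarity: no positive eigenvalue above tolerance "
            "(all points coincide)"
        )
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return Embedding(coords, eigval[keep])


def kmeans_partition(
    e: Embedding,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> Partition:
    """Best-inertia K-means over ``restarts`` initializations.

    Labels are compacted to 1..k' where k' <= k counts non-empty clusters.
    """
    n = e.coordinates.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must be in [1, N={n}]")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
    )
    raw = km.fit_predict(e.coordinates)
    _, compact = np.unique(raw, return_inverse=True)
    return Partition(compact + 1)


# ---------------------------------------------------------------------------
# One base-clustering run


def rf_cluster_once(g, cfg: ForestConfig, k: int, seed: int | None = None) -> Partition:
    """Synthetic class -> forest -> proximity -> sqrt(1-S) -> MDS -> K-means."""
    if seed is not None:
        cfg = ForestConfig(cfg.ntrees, cfg.max_leaf_nodes, cfg.mtry, cfg.n_synth, seed)
    model = RandomForestClustering(
        n_clusters=k,
        ntrees=cfg.ntrees,
        max_leaf_nodes=cfg.max_leaf_nodes,
        mtry=cfg.mtry,
        n_synth=cfg.n_synth,
        random_state=cfg.seed,
    )
    model.fit(_as_matrix(g))
    return Partition(model.labels_ + 1)


class RandomForestClustering(ClusterMixin, BaseEstimator):
    """Single-run unsupervised random-forest clustering.

    Parameters
    ----------
    n_clusters : number of clusters k for the K-means stage.
    ntrees : trees per forest.
    max_leaf_nodes : hard best-first leaf cap MN (default ceil(sqrt(N))).
    mtry : candidate markers per split (default floor(sqrt(l))).
    n_synth : synthetic-class size (default N, balanced classes).
    kmeans_restarts, kmeans_max_iter : K-means search effort.
    random_state : seed; the whole run is deterministic given it.

    Attributes
    ----------
    labels_ : (N,) 0-based cluster labels.
    proximity_ : (N, N) share-a-leaf fractions.
    dissimilarity_ : sqrt(1 - proximity_).
    embedding_ : classical-scaling :class:`Embedding`.
    forest_ : the fitted :class:`Forest`.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        ntrees: int = 500,
        max_leaf_nodes: int | None = None,
        mtry: int | None = None,
        n_synth: int | None = None,
        kmeans_restarts: int = 10,
        kmeans_max_iter: int = 300,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.ntrees = ntrees
        self.max_leaf_nodes = max_leaf_nodes
        self.mtry = mtry
        self.n_synth = n_synth
        self.kmeans_restarts = kmeans_restarts
        self.kmeans_max_iter = kmeans_max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        cfg = ForestConfig(
            ntrees=self.ntrees,
            max_leaf_nodes=self.max_leaf_nodes,
            mtry=self.mtry,
            n_synth=self.n_synth,
            seed=self.random_state,
        )
        self.forest_ = build_unsupervised_forest(X, cfg)
        self.proximity_ = compute_proximity(self.forest_, X)
        self.dissimilarity_ = proximity_to_dissimilarity(self.proximity_)
        self.embedding_ = classical_mds(self.dissimilarity_)
        km_seed = np.random.SeedSequence(self.random_state).generate_state(2)[1]
        part = kmeans_partition(
            self.embedding_,
            self.n_clusters,
            seed=int(km_seed % (2**31)),
            restarts=self.kmeans_restarts,
            max_iter=self.kmeans_max_iter,
        )
        self.labels_ = part.assignment - 1
        return self
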