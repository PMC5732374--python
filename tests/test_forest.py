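import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfclue import (
    ForestConfig,
    RandomForestClustering,
    build_unsupervised_forest,
    classical_mds,
    compute_proximity,
    generate_synthetic_class,
    gini_gain,
    gini_impurity,
    kmeans_partition,
    nmi,
    proximity_to_dissimilarity,
    rf_cluster_once,
)
from rfclue.errors import DegenerateInputError, ValidationError
from rfclue.forest import Embedding

from _oracles import brute_best_two_partition, brute_proximity


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375)],
    )
    def test_impurity_hand_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_impurity_rejects_empty_node(self):
        with pytest.raises(ValidationError):
            gini_impurity([0, 0])

    @pytest.mark.parametrize(
        "parent,left,right,expected",
        [
            ((5, 5), (5, 0), (0, 5), 0.5),  # perfect split
            ((4, 4), (2, 2), (2, 2), 0.0),  # children replicate parent
            ((4, 4), (4, 4), (0, 0), 0.0),  # non-splitting split
        ],
    )
    def test_gain_hand_values(self, parent, left, right, expected):
        assert gini_gain(parent, left, right) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=1, max_size=4)
    )
    def test_gain_nonnegative_for_any_split(self, pairs):
        left = [p[0] for p in pairs]
        right = [p[1] for p in pairs]
        parent = [l + r for l, r in zip(left, right)]
        if sum(parent) == 0:
            return
        assert gini_gain(parent, left, right) >= -1e-12


class TestSyntheticClass:
    def test_constant_marker_stays_constant(self, rng):
        g = np.column_stack([np.full(20, 2), rng.integers(0, 3, 20)])
        synth = generate_synthetic_class(g, 50, rng)
        assert (synth[:, 0] == 2).all()

    def test_marginals_preserved_within_3_se(self, rng):
        col = np.array([0] * 10 + [1] * 5 + [2] * 5)  # freqs 0.5/0.25/0.25
        g = col[:, None]
        synth = generate_synthetic_class(g, 10_000, rng)[:, 0]
        for value, p in [(0, 0.5), (1, 0.25), (2, 0.25)]:
            freq = (synth == value).mean()
            se = math.sqrt(p * (1 - p) / 10_000)
            assert abs(freq - p) < 3 * se

    def test_correlated_markers_become_independent(self, rng):
        col = rng.integers(0, 3, 40)
        g = np.column_stack([col, col])  # perfectly correlated
        synth = generate_synthetic_class(g, 10_000, rng)
        r = np.corrcoef(synth[:, 0], synth[:, 1])[0, 1]
        assert abs(r) < 3 / math.sqrt(10_000)


class TestForest:
    def test_leaf_cap_of_two_gives_single_split(self, rng):
        g = rng.integers(0, 3, size=(15, 20))
        forest = build_unsupervised_forest(g, ForestConfig(ntrees=1, max_leaf_nodes=2, seed=1))
        assert len(np.unique(forest.apply(g))) <= 2

    def test_same_seed_identical_leaves(self, rng):
        g = rng.integers(0, 3, size=(20, 30))
        cfg = ForestConfig(ntrees=20, seed=9)
        f1 = build_unsupervised_forest(g, cfg)
        f2 = build_unsupervised_forest(g, cfg)
        assert np.array_equal(f1.apply(g), f2.apply(g))

    def test_mtry_exceeding_markers_rejected(self, rng):
        g = rng.integers(0, 3, size=(10, 5))
        with pytest.raises(ValidationError, match="mtry"):
            build_unsupervised_forest(g, ForestConfig(ntrees=5, mtry=6))

    def test_structured_data_separable_from_synthetic_class(self, two_pop_sim):
        # population structure induces marker correlations the synthetic
        # independent-marginals class lacks, so OOB error is well below chance
        g, _ = two_pop_sim
        forest = build_unsupervised_forest(g, ForestConfig(ntrees=200, seed=3))
        assert forest.oob_error < 0.4


class TestProximity:
    def test_single_tree_same_leaf_pair(self, rng):
        g = np.vstack([np.zeros((4, 10), dtype=int), np.full((4, 10), 2, dtype=int)])
        forest = build_unsupervised_forest(g, ForestConfig(ntrees=1, max_leaf_nodes=2, seed=0))
        s = compute_proximity(forest, g)
        leaves = forest.apply(g)[:, 0]
        i, j = 0, 1
        expected = 1.0 if leaves[i] == leaves[j] else 0.0
        assert s[i, j] == expected

    def test_matches_per_tree_brute_force(self, rng):
        g = rng.integers(0, 3, size=(6, 12))
        forest = build_unsupervised_forest(g, ForestConfig(ntrees=5, seed=2))
        s = compute_proximity(forest, g)
        assert np.array_equal(s, brute_proximity(forest.apply(g)))

    def test_invariants(self, rng):
        g = rng.integers(0, 3, size=(12, 15))
        ntrees = 7
        forest = build_unsupervised_forest(g, ForestConfig(ntrees=ntrees, seed=4))
        s = compute_proximity(forest, g)
        assert np.array_equal(s, s.T)
        assert np.all(np.diag(s) == 1.0)
        assert np.all((s >= 0) & (s <= 1))
        assert np.allclose(s * ntrees, np.round(s * ntrees))  # multiples of 1/ntrees


class TestDissimilarity:
    @pytest.mark.parametrize("s,expected", [(1.0, 0.0), (0.0, 1.0), (0.75, 0.5)])
    def test_elementwise_sqrt(self, s, expected):
        m = np.array([[1.0, s], [s, 1.0]])
        d = proximity_to_dissimilarity(m)
        assert d[0, 1] == pytest.approx(expected)
        assert d[0, 0] == 0.0


class TestClassicalMDS:
    def test_collinear_points_embed_in_one_dimension(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        emb = classical_mds(d)
        assert emb.p == 1
        x = emb.coordinates[:, 0]
        recovered = np.abs(x[:, None] - x[None, :])
        assert np.allclose(recovered, d, atol=1e-10)

    def test_equilateral_triangle_embeds_in_plane(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = classical_mds(d)
        assert emb.p == 2
        diff = emb.coordinates[:, None, :] - emb.coordinates[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        assert np.allclose(dist, d, atol=1e-10)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(10, 3))
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        emb = classical_mds(d)
        ediff = emb.coordinates[:, None, :] - emb.coordinates[None, :, :]
        edist = np.sqrt((ediff**2).sum(-1))
        assert np.allclose(edist, d, rtol=1e-8, atol=1e-10)

    def test_all_zero_dissimilarity_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="degenerate"):
            classical_mds(np.zeros((4, 4)))


class TestKMeansPartition:
    def test_k_one_collapses(self, rng):
        emb = Embedding(rng.normal(size=(8, 2)), np.ones(2))
        part = kmeans_partition(emb, 1, seed=0)
        assert part.n_clusters_nonempty == 1

    def test_k_equals_n_gives_singletons(self, rng):
        emb = Embedding(rng.normal(size=(6, 2)), np.ones(2))
        part = kmeans_partition(emb, 6, seed=0)
        assert part.n_clusters_nonempty == 6

    def test_k_above_n_rejected(self, rng):
        emb = Embedding(rng.normal(size=(4, 2)), np.ones(2))
        with pytest.raises(ValidationError):
            kmeans_partition(emb, 5, seed=0)

    def test_separated_clouds_match_exhaustive_optimum(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (4, 2))])
        emb = Embedding(pts, np.ones(2))
        part = kmeans_partition(emb, 2, seed=1)
        best, _ = brute_best_two_partition(pts)
        assert nmi(part.assignment, best + 1) == pytest.approx(1.0)


class TestRfClusterOnce:
    def test_deterministic_given_seed(self, small_sim):
        g, _ = small_sim
        cfg = ForestConfig(ntrees=60)
        p1 = rf_cluster_once(g, cfg, 3, seed=42)
        p2 = rf_cluster_once(g, cfg, 3, seed=42)
        assert np.array_equal(p1.assignment, p2.assignment)

    def test_k_bound_respected(self, two_pop_sim):
        g, _ = two_pop_sim  # N=60, ceil(sqrt(60)) = 8
        part = rf_cluster_once(g, ForestConfig(ntrees=60), 8, seed=0)
        assert part.n_clusters_nonempty <= 8

    def test_recovers_two_population_structure(self, two_pop_sim):
        # 60 individuals, 300 markers, fst=0.3: one run should almost
        # always align closely with truth
        g, truth = two_pop_sim
        hits = 0
        for seed in range(20):
            part = rf_cluster_once(g, ForestConfig(ntrees=500), 2, seed=seed)
            if nmi(part, truth) >= 0.8:
                hits += 1
        assert hits >= 18

    def test_estimator_exposes_fitted_artifacts(self, small_sim):
        g, _ = small_sim
        model = RandomForestClustering(n_clusters=3, ntrees=40, random_state=0).fit(g.values)
        n = g.n_individuals
        assert model.labels_.shape == (n,)
        assert model.proximity_.shape == (n, n)
        assert model.dissimilarity_.shape == (n, n)
        assert model.embedding_.p < n


def test_divergence_does_not_hurt_recovery():
    """Median single-run NMI is non-decreasing in the divergence knob."""
    from rfclue import SimulationConfig, simulate_populations

    medians = []
    for fst in (0.05, 0.15, 0.3):
        g, truth = simulate_populations(SimulationConfig(2, 20, 200, fst=fst, seed=31))
        scores = [
            nmi(rf_cluster_once(g, ForestConfig(ntrees=150), 2, seed=s), truth)
            for s in range(20)
        ]
        medians.append(np.median(scores))
    assert medians[0] <= medians[1] + 1e-9
    assert medians[1] <= medians[2] + 1e-9
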