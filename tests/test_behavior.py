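"""Behavioral similarity estimation, PCA, and category discovery tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from foodnet import simulate
from foodnet.behavior import (
    FoodSimilarityMatrix,
    pc_rdm,
    pca_similarity,
    select_k_kmeans,
    similarity_rdm,
    triplet_similarity_matrix,
)


def _sim_from_values(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    counts = np.full((n, n), 10, dtype=int)
    np.fill_diagonal(counts, 0)
    return FoodSimilarityMatrix(values=values, n_pairs_observed=counts)


class TestTripletSimilarity:
    def test_single_triplet_proportions(self):
        trip = pd.DataFrame({"item_a": [1], "item_b": [2], "item_c": [3], "odd": [3]})
        s = triplet_similarity_matrix(trip, 3)
        assert s.values[0, 1] == 1.0
        assert s.values[0, 2] == 0.0
        assert s.values[1, 2] == 0.0
        assert np.allclose(np.diag(s.values), 1.0)

    def test_full_enumeration_pair_coverage(self, default_space, rng):
        # every pair of 36 items co-occurs with each of the 34 remaining items
        trips = simulate.gen_triplet_responses(default_space, 1, 0.15, rng)
        assert len(trips) == 7140
        s = triplet_similarity_matrix(trips, 36)
        off = ~np.eye(36, dtype=bool)
        assert (s.n_pairs_observed[off] == 34).all()
        assert s.fully_observed

    def test_deterministic_choices_recover_distance_order(self, rng):
        # 1-D space, near-zero temperature: similarity ranks distances
        coords = np.linspace(0.0, 2.5, 12)[:, None]
        space = simulate.FoodSpace(
            coords=coords,
            category_label=np.ones(12, dtype=int),
            processing_score=coords[:, 0],
            hedonic_score=np.zeros(12),
        )
        trips = simulate.gen_triplet_responses(space, 20, 1e-8, rng)
        s = triplet_similarity_matrix(trips, 12)
        iu = np.triu_indices(12, 1)
        dist = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        rho = spearmanr(s.values[iu], -dist[iu]).statistic
        assert rho >= 0.95

    def test_unobserved_pairs_flagged(self):
        trip = pd.DataFrame({"item_a": [1], "item_b": [2], "item_c": [3], "odd": [1]})
        s = triplet_similarity_matrix(trip, 5)
        assert np.isnan(s.values[3, 4])
        assert not s.fully_observed

    @pytest.mark.parametrize(
        "frame",
        [
            pd.DataFrame(columns=["item_a", "item_b", "item_c", "odd"]),
            pd.DataFrame({"item_a": [0], "item_b": [2], "item_c": [3], "odd": [2]}),
            pd.DataFrame({"item_a": [1], "item_b": [1], "item_c": [3], "odd": [1]}),
            pd.DataFrame({"item_a": [1], "item_b": [2], "item_c": [3], "odd": [4]}),
        ],
    )
    def test_invalid_input_rejected(self, frame):
        with pytest.raises(ValueError):
            triplet_similarity_matrix(frame, 5)

    def test_estimator_consistency_with_repetitions(self, rng):
        # error vs the closed-form choice-model proportions shrinks with reps
        coords = np.array([[0.0, 0], [0.5, 0], [1.2, 0.4], [2.0, 0.1], [0.8, 1.0]])
        space = simulate.FoodSpace(
            coords=coords,
            category_label=np.ones(5, dtype=int),
            processing_score=coords[:, 0],
            hedonic_score=np.zeros(5),
        )
        sim = space.similarity()
        import itertools

        expected = np.zeros((5, 5))
        counts = np.zeros((5, 5))
        for a, b, c in itertools.combinations(range(5), 3):
            util = np.array([sim[b, c], sim[a, c], sim[a, b]]) / 0.3
            p = np.exp(util - util.max())
            p /= p.sum()
            for (i, j), surv in [((b, c), p[0]), ((a, c), p[1]), ((a, b), p[2])]:
                expected[i, j] += surv
                expected[j, i] += surv
                counts[i, j] += 1
                counts[j, i] += 1
        np.fill_diagonal(counts, 1)
        expected /= counts
        errs = []
        for reps in (20, 2000):
            trips = simulate.gen_triplet_responses(space, reps, 0.3, rng)
            s = triplet_similarity_matrix(trips, 5)
            iu = np.triu_indices(5, 1)
            errs.append(np.abs(s.values[iu] - expected[iu]).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.05


class TestPCA:
    def test_rank_two_matrix_concentrates_variance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 2))
        values = a @ a.T  # rank 2; centering can only shrink the rank
        sim = _sim_from_values(values)
        res = pca_similarity(sim)
        assert res.variance_fraction[:2].sum() == pytest.approx(1.0, abs=1e-10)

    def test_exchangeable_matrix_has_flat_spectrum(self):
        # diag 1, constant off-diagonal: all nonzero eigenvalues equal
        values = np.full((8, 8), 0.4)
        np.fill_diagonal(values, 1.0)
        res = pca_similarity(_sim_from_values(values))
        nonzero = res.variance_fraction[res.variance_fraction > 1e-12]
        assert np.allclose(nonzero, nonzero[0], atol=1e-10)

    def test_scores_translation_invariant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.9, size=(7, 7))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        r1 = pca_similarity(_sim_from_values(base))
        # a constant shift of the matrix is removed exactly by centering
        r2 = pca_similarity(_sim_from_values(base + 0.05))
        assert np.allclose(np.abs(r1.scores), np.abs(r2.scores), atol=1e-8)

    def test_first_score_tracks_processing_axis(self, default_space, rng):
        trips = simulate.gen_triplet_responses(default_space, 5, 0.15, rng)
        s = triplet_similarity_matrix(trips, 36)
        res = pca_similarity(s)
        rho = spearmanr(res.scores[:, 0], default_space.processing_score).statistic
        assert abs(rho) >= 0.9

    def test_flagged_entries_rejected(self):
        values = np.eye(4)
        counts = np.zeros((4, 4), dtype=int)
        sim = FoodSimilarityMatrix(values=values, n_pairs_observed=counts)
        with pytest.raises(ValueError):
            pca_similarity(sim)


class TestKMeansSelection:
    def test_three_planted_clusters_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [6, 0], [3, 6]], dtype=float)
        truth = np.repeat([0, 1, 2], 12)
        pts = centers[truth] + rng.normal(0, 0.3, size=(36, 2))
        labels, sil, k = select_k_kmeans(pts, k_range=range(2, 8))
        assert k == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicated_points_give_unit_silhouette(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        labels, sil, k = select_k_kmeans(pts, k_range=range(2, 3), n_init=5)
        assert sil[2] == pytest.approx(1.0)

    def test_default_cohort_selects_planted_category_count(self):
        cfg = simulate.SyntheticConfig(seed=7)
        rng = cfg.rng()
        space = simulate.gen_food_space(cfg, rng)
        trips = simulate.gen_triplet_responses(space, 5, 0.15, rng)
        s = triplet_similarity_matrix(trips, 36)
        res = pca_similarity(s)
        labels, _, k = select_k_kmeans(res.scores[:, :2])
        assert k == 5
        assert adjusted_rand_score(space.category_label, labels) == 1.0

    def test_modal_k_stable_across_seeds(self):
        ks = []
        for seed in range(10):
            cfg = simulate.SyntheticConfig(seed=seed)
            rng = cfg.rng()
            space = simulate.gen_food_space(cfg, rng)
            trips = simulate.gen_triplet_responses(space, 5, 0.15, rng)
            s = triplet_similarity_matrix(trips, 36)
            res = pca_similarity(s)
            _, _, k = select_k_kmeans(res.scores[:, :2])
            ks.append(k)
        assert sum(k == 5 for k in ks) >= 8

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError):
            select_k_kmeans(np.random.default_rng(0).normal(size=(10, 2)), k_range=range(0))


class TestModelRDMs:
    def test_pc_rdm_absolute_differences(self):
        from foodnet.behavior import PCAResult

        scores = np.array([[0.0], [1.0], [3.0]])

        pca = PCAResult(scores=scores, loadings=scores, variance_fraction=np.array([1.0]))
        r = pc_rdm(pca, 1)
        assert r.d[0, 1] == 1.0 and r.d[0, 2] == 3.0 and r.d[1, 2] == 2.0
        assert np.allclose(np.diag(r.d), 0.0)
        # sign invariance
        pca_neg = PCAResult(
            scores=-scores, loadings=scores, variance_fraction=np.array([1.0])
        )
        assert np.allclose(pc_rdm(pca_neg, 1).d, r.d)
        with pytest.raises(ValueError):
            pc_rdm(pca, 2)

    def test_similarity_rdm_involution(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0.2, 0.8, size=(6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = _sim_from_values(values)
        r = similarity_rdm(sim)
        assert r.d[1, 2] == pytest.approx(1.0 - values[1, 2])
        restored = 1.0 - r.d
        np.fill_diagonal(restored, 1.0)
        assert np.allclose(restored, values)
        # all-ones similarity -> all-zero RDM
        ones = _sim_from_values(np.ones((4, 4)))
        assert np.allclose(similarity_rdm(ones).d, 0.0)
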