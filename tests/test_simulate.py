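"""Generator tests: planted structure must be present and recoverable."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from foodnet import rdm, simulate
from foodnet.simulate import SyntheticConfig, gen_food_space, gen_triplet_responses


class TestConfig:
    def test_defaults_mirror_study_scale(self):
        cfg = SyntheticConfig()
        cfg.validate()
        assert (cfg.n_subjects, cfg.n_items, cfg.n_categories) == (43, 36, 5)
        assert cfg.n_rois == 17

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_items": 2},
            {"choice_temperature": 0.0},
            {"pattern_noise_sd": -1.0},
            {"n_subjects": 0},
            {"volume_shape": (16, 16)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            replace(SyntheticConfig(), **kwargs).validate()


class TestFoodSpace:
    def test_single_category_zero_spread_degenerates(self, rng):
        cfg = replace(SyntheticConfig(n_categories=1), category_spread=0.0)
        space = gen_food_space(cfg, rng)
        assert np.allclose(space.coords, space.coords[0])
        assert np.allclose(space.similarity(), 1.0)

    def test_planted_categories_are_separated(self, default_space):
        # silhouette of the true labels on the generated coordinates
        sil = silhouette_score(default_space.coords, default_space.category_label)
        assert sil > 0.6

    def test_default_space_has_all_categories(self, default_space):
        assert default_space.n_items == 36
        assert sorted(set(default_space.category_label)) == [1, 2, 3, 4, 5]

    def test_similarity_kernel_range_and_symmetry(self, default_space):
        s = default_space.similarity()
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 1.0)
        assert (s > 0).all() and (s <= 1).all()

    def test_same_seed_reproducible_different_seed_not(self):
        cfg = SyntheticConfig(seed=11)
        a = gen_food_space(cfg, cfg.rng())
        b = gen_food_space(cfg, cfg.rng())
        c = gen_food_space(replace(cfg, seed=12), replace(cfg, seed=12).rng())
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)


class TestTriplets:
    @pytest.mark.parametrize("n", [3, 5, 8, 12, 20, 40])
    def test_full_enumeration_count(self, n, rng):
        space = simulate.FoodSpace(
            coords=rng.normal(size=(n, 2)),
            category_label=np.ones(n, dtype=int),
            processing_score=np.zeros(n),
            hedonic_score=np.zeros(n),
        )
        trips = gen_triplet_responses(space, reps=1, temperature=1.0, rng=rng)
        assert len(trips) == math.comb(n, 3)

    def test_zero_temperature_limit_picks_far_item(self, rng):
        # one item far away: the remaining near pair always survives
        coords = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0]])
        space = simulate.FoodSpace(
            coords=coords,
            category_label=np.array([1, 1, 1]),
            processing_score=coords[:, 0],
            hedonic_score=np.zeros(3),
        )
        trips = gen_triplet_responses(space, reps=200, temperature=1e-9, rng=rng)
        assert (trips["odd"] == 3).all()

    def test_choice_frequencies_match_softmax(self, rng):
        # 4 items -> 4 triplets; empirical odd frequencies vs closed form
        coords = np.array([[0.0, 0.0], [0.4, 0.0], [1.0, 0.3], [1.7, 0.1]])
        space = simulate.FoodSpace(
            coords=coords,
            category_label=np.ones(4, dtype=int),
            processing_score=coords[:, 0],
            hedonic_score=np.zeros(4),
        )
        temp, reps = 0.15, 1000
        sim = space.similarity()
        trips = gen_triplet_responses(space, reps=reps, temperature=temp, rng=rng)
        import itertools

        for (a, b, c) in itertools.combinations(range(4), 3):
            block = trips[
                (trips.item_a == a + 1) & (trips.item_b == b + 1) & (trips.item_c == c + 1)
            ]
            util = np.array([sim[b, c], sim[a, c], sim[a, b]]) / temp
            p = np.exp(util - util.max())
            p /= p.sum()
            for prob, item in zip(p, (a, b, c)):
                freq = (block["odd"] == item + 1).mean()
                se = np.sqrt(prob * (1 - prob) / reps)
                assert abs(freq - prob) <= 3 * se + 1e-12

    def test_temperature_must_be_positive(self, default_space, rng):
        with pytest.raises(ValueError):
            gen_triplet_responses(default_space, 1, 0.0, rng)


class TestROIPatterns:
    def test_cohort_shape_matches_config(self, small_cohort):
        cfg, _, cohort = small_cohort
        assert len(cohort.patterns) == cfg.n_subjects
        assert all(len(r) == cfg.n_rois for r in cohort.patterns.values())
        nets = list(cohort.roi_network.values())
        assert nets.count(1) == cfg.n_rois_net1
        assert nets.count(2) == cfg.n_rois_net2
        assert nets.count(0) == cfg.n_outlier_rois

    def test_default_cohort_dimensions(self):
        cfg = SyntheticConfig(seed=0, n_subjects=2)
        rng = cfg.rng()
        cohort = simulate.gen_roi_patterns(cfg, gen_food_space(cfg, rng), rng)
        assert len(cohort.roi_ids) == 17
        p = cohort.patterns["sub01"]["roi01"]
        assert p.betas.shape == (36, 120)

    def test_noiseless_patterns_recover_target_exactly(self):
        cfg = replace(
            SyntheticConfig(seed=3, n_subjects=2, n_items=12, voxels_per_roi=40),
            pattern_noise_sd=0.0,
            subject_amp_sd=0.0,
        )
        rng = cfg.rng()
        cohort = simulate.gen_roi_patterns(cfg, gen_food_space(cfg, rng), rng)
        for rois in cohort.patterns.values():
            for roi, pat in rois.items():
                target = cohort.target_rdms[cohort.roi_network[roi]]
                emp = rdm.compute_rdm(pat)
                assert np.allclose(emp.d, target.d, atol=1e-8)
                rho = spearmanr(rdm.upper_tri(emp), rdm.upper_tri(target)).statistic
                assert rho >= 0.95

    def test_same_network_noiseless_rois_agree(self):
        cfg = replace(
            SyntheticConfig(seed=5, n_subjects=1, n_items=10, voxels_per_roi=30),
            pattern_noise_sd=0.0,
        )
        rng = cfg.rng()
        cohort = simulate.gen_roi_patterns(cfg, gen_food_space(cfg, rng), rng)
        net1 = [r for r, n in cohort.roi_network.items() if n == 1][:2]
        v1 = rdm.upper_tri(rdm.compute_rdm(cohort.patterns["sub01"][net1[0]]))
        v2 = rdm.upper_tri(rdm.compute_rdm(cohort.patterns["sub01"][net1[1]]))
        assert np.corrcoef(v1, v2)[0, 1] > 0.999

    def test_target_rdms_are_valid(self, small_cohort):
        _, _, cohort = small_cohort
        for target in cohort.target_rdms.values():
            assert np.allclose(target.d, target.d.T)
            assert np.allclose(np.diag(target.d), 0.0)
            assert (target.d >= 0).all() and (target.d <= 2).all()

    def test_determinism(self):
        cfg = SyntheticConfig(seed=9, n_subjects=2, n_items=8, voxels_per_roi=20)
        runs = []
        for _ in range(2):
            rng = cfg.rng()
            cohort = simulate.gen_roi_patterns(cfg, gen_food_space(cfg, rng), rng)
            runs.append(cohort.patterns["sub02"]["roi03"].betas)
        assert np.array_equal(runs[0], runs[1])


class TestSearchlightDataset:
    def test_truth_region_fraction_and_shape(self, rng):
        cfg = SyntheticConfig(seed=2)
        ds = simulate.gen_searchlight_dataset(cfg, rng, truth_fraction=0.3)
        frac = ds.truth.sum() / ds.mask.sum()
        assert 0.2 <= frac <= 0.4
        assert ds.volumes.shape == (36, 16, 16, 10)
        # min truth dimension >= one sphere diameter at radius 3
        nzs = np.nonzero(ds.truth)
        assert min(int(np.ptp(a)) + 1 for a in nzs) >= 7

    def test_zero_fraction_means_no_truth(self, rng):
        ds = simulate.gen_searchlight_dataset(
            SyntheticConfig(seed=2), rng, truth_fraction=0.0
        )
        assert not ds.truth.any()

    def test_too_small_volume_rejected(self, rng):
        cfg = replace(SyntheticConfig(seed=2), volume_shape=(6, 16, 10))
        with pytest.raises(ValueError):
            simulate.gen_searchlight_dataset(cfg, rng)


class TestPSCDataset:
    def test_zero_noise_perfect_rating_correlation(self, default_space):
        cfg = SyntheticConfig(seed=1, n_subjects=3)
        psc = simulate.gen_psc_dataset(
            cfg, default_space, cfg.rng(), rating_noise_sd=0.0
        )
        wide = psc.ratings.pivot_table(
            index=["subject", "item"], columns="condition", values="rating"
        )
        r = np.corrcoef(wide["pleasantness"], wide["self_control"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_default_between_subject_rating_correlation(self, default_space):
        cfg = SyntheticConfig(seed=1)
        psc = simulate.gen_psc_dataset(cfg, default_space, cfg.rng())
        wide = psc.ratings[psc.ratings.condition == "pleasantness"].pivot(
            index="item", columns="subject", values="rating"
        )
        cc = np.corrcoef(wide.to_numpy().T)
        mean_r = cc[np.triu_indices_from(cc, 1)].mean()
        assert mean_r >= 0.9

    def test_planted_modulation_pattern(self, default_space):
        cfg = SyntheticConfig(seed=1)
        psc = simulate.gen_psc_dataset(cfg, default_space, cfg.rng())
        assert psc.mod_truth[(1, "pleasantness")] < 0 < psc.mod_truth[(1, "self_control")]
        assert psc.mod_truth[(2, "pleasantness")] == psc.mod_truth[(2, "self_control")] > 0
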