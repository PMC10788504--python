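"""Permutation statistics: BH, edge test, reliability, nodes, hit/miss, correlation."""

from itertools import combinations

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import avalanchebci as ab
from avalanchebci.avalanches import TrialATMSet


def atm_set(matrices, conditions, outcomes=None, subject_id="s"):
    matrices = np.asarray(matrices, dtype=float)
    return TrialATMSet(
        subject_id=subject_id,
        matrices=matrices,
        has_avalanches=np.ones(len(matrices), dtype=bool),
        condition_labels=np.asarray(conditions),
        outcome_labels=None if outcomes is None else np.asarray(outcomes),
        threshold_z=3.0,
        bin_length_samples=1,
        n_avalanches_per_trial=np.ones(len(matrices), dtype=int),
    )


class TestBHCorrect:
    def test_hand_worked_step_up(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06]
        reject, thr = ab.bh_correct(p, alpha=0.05)
        assert reject.tolist() == [True, True, False, False, False, False]
        assert thr == 0.008

    def test_all_ones_rejects_nothing(self):
        reject, _ = ab.bh_correct(np.ones(10), 0.05)
        assert not reject.any()

    def test_all_zeros_rejects_everything(self):
        reject, _ = ab.bh_correct(np.zeros(7), 0.05)
        assert reject.all()

    def test_empty_input_empty_output(self):
        reject, thr = ab.bh_correct([], 0.05)
        assert reject.size == 0 and thr == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_fdr_bh(self, seed):
        p = np.random.default_rng(seed).random(200) ** 2
        ours, _ = ab.bh_correct(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, ref)


def edge_test_oracle(mats, n_mi):
    """Independent exhaustive enumeration of the two-sided permutation test."""
    n = len(mats)
    flat = mats.reshape(n, -1)
    obs = flat[:n_mi].mean(0) - flat[n_mi:].mean(0)
    nulls = []
    for chosen in combinations(range(n), n_mi):
        rest = [k for k in range(n) if k not in chosen]
        nulls.append(flat[list(chosen)].mean(0) - flat[rest].mean(0))
    nulls = np.abs(np.array(nulls))
    return (nulls >= np.abs(obs)[None, :]).mean(axis=0)


class TestSubjectEdgeTest:
    def test_identical_condition_ensembles_yield_exact_null(self):
        rng = np.random.default_rng(0)
        block = rng.random((3, 4, 4))
        mats = np.concatenate([block, block])
        res = ab.subject_edge_test(
            atm_set(mats, ["MI"] * 3 + ["Rest"] * 3), n_permutations=500, rng_seed=0
        )
        np.testing.assert_allclose(res.observed_diff, 0.0, atol=1e-15)
        assert not res.significant.any()

    def test_exhaustive_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        mats = rng.random((6, 3, 3))
        res = ab.subject_edge_test(
            atm_set(mats, ["MI"] * 3 + ["Rest"] * 3), n_permutations=10_000
        )
        assert res.exhaustive and res.n_permutations == 20
        oracle = edge_test_oracle(mats, 3).reshape(3, 3)
        np.testing.assert_allclose(res.p_values, oracle, atol=0)

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(6)
        mats = rng.random((8, 3, 3))
        labels = ["MI"] * 4 + ["Rest"] * 4
        mc = ab.subject_edge_test(
            atm_set(mats, labels), n_permutations=4000, rng_seed=3, exhaustive=False
        )
        ex = ab.subject_edge_test(atm_set(mats, labels), n_permutations=70)
        assert ex.exhaustive
        assert np.abs(mc.p_values - ex.p_values).max() < 2 / np.sqrt(4000)

    def test_p_floor_and_determinism(self):
        rng = np.random.default_rng(7)
        mats = rng.random((30, 2, 2))
        mats[:15] += 5.0  # enormous effect
        labels = ["MI"] * 15 + ["Rest"] * 15
        a = ab.subject_edge_test(atm_set(mats, labels), n_permutations=999, rng_seed=1,
                                 exhaustive=False)
        b = ab.subject_edge_test(atm_set(mats, labels), n_permutations=999, rng_seed=1,
                                 exhaustive=False)
        assert a.p_values.min() == pytest.approx(1 / 1000)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_degenerate_single_class_rejected(self):
        mats = np.random.default_rng(0).random((4, 2, 2))
        with pytest.raises(ValueError, match="per condition"):
            ab.subject_edge_test(atm_set(mats, ["MI"] * 4), n_permutations=10)

    def test_trials_without_avalanches_excluded(self):
        rng = np.random.default_rng(1)
        mats = rng.random((6, 2, 2))
        s = atm_set(mats, ["MI"] * 3 + ["Rest"] * 3)
        s.has_avalanches[0] = False
        res = ab.subject_edge_test(s, n_permutations=50)
        expected = mats[1:3].mean(0) - mats[3:].mean(0)
        np.testing.assert_allclose(res.observed_diff, expected)


def make_edge_result(significant, subject_id="s"):
    sig = np.asarray(significant, dtype=bool)
    return ab.EdgeTestResult(
        subject_id=subject_id,
        observed_diff=np.zeros_like(sig, dtype=float),
        p_values=np.where(sig, 1e-4, 0.5),
        significant=sig,
        n_permutations=10_000,
        bh_threshold=0.0,
        exhaustive=False,
    )


class TestGroupReliability:
    def test_no_significant_edges_anywhere(self):
        results = [make_edge_result(np.zeros((6, 6))) for _ in range(5)]
        rel = ab.group_reliability(results, n_permutations=200, rng_seed=0)
        assert not rel.reliable.any()
        assert (rel.p_values == 1.0).all()

    def test_shared_sparse_edge_is_reliable(self):
        # one edge significant in all 20 subjects at ~1% density: the
        # permutation p hits its floor, far below the binomial tail
        # (density ^ 20), and must survive BH
        n_regions = 10
        results = []
        for s in range(20):
            sig = np.zeros((n_regions, n_regions), dtype=bool)
            sig[2, 3] = True  # the shared edge (density 1/100)
            results.append(make_edge_result(sig, subject_id=f"s{s}"))
        rel = ab.group_reliability(results, n_permutations=2000, alpha=0.05, rng_seed=1)
        assert rel.concordance_counts[2, 3] == 20
        assert rel.p_values[2, 3] == pytest.approx(1 / 2001)
        assert rel.reliable[2, 3]

    def test_random_placement_controls_false_discoveries(self):
        # per-subject significant edges placed uniformly at random: the
        # fraction of edges declared reliable stays at/below alpha on average
        n_regions, n_edges = 8, 64
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            results = []
            for s in range(10):
                sig = np.zeros(n_edges, dtype=bool)
                sig[rng.choice(n_edges, size=6, replace=False)] = True
                results.append(make_edge_result(sig.reshape(n_regions, n_regions)))
            rel = ab.group_reliability(results, n_permutations=300, rng_seed=seed + 100)
            rates.append(rel.reliable.mean())
        assert np.mean(rates) <= 0.05


class TestNodeConcordance:
    def test_empty_matrix_nothing_significant(self):
        res = ab.node_concordance(np.zeros((6, 6), dtype=bool), n_permutations=100)
        assert not res.significant.any()
        assert (res.p_values == 1.0).all()

    def test_degree_counts_in_plus_out_with_diagonal_once(self):
        rel = np.zeros((4, 4), dtype=bool)
        rel[0, 1] = rel[2, 0] = rel[0, 0] = True
        res = ab.node_concordance(rel, n_permutations=10, rng_seed=0)
        assert res.degree.tolist() == [3, 1, 1, 0]

    def test_hub_region_detected(self):
        n_regions = 20
        rel = np.zeros((n_regions, n_regions), dtype=bool)
        rel[5, :10] = True  # all reliable edges emanate from region 5
        res = ab.node_concordance(rel, n_permutations=2000, alpha=0.05, rng_seed=2)
        assert res.significant[5]

    def test_uniform_placement_controls_false_positives(self):
        n_regions = 10
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rel = np.zeros(n_regions * n_regions, dtype=bool)
            rel[rng.choice(rel.size, size=8, replace=False)] = True
            res = ab.node_concordance(
                rel.reshape(n_regions, n_regions), n_permutations=300, rng_seed=seed + 7
            )
            rates.append(res.significant.mean())
        assert np.mean(rates) <= 0.05


class TestHitMissContrast:
    @staticmethod
    def _labeled_set(seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        n = 40
        conditions = np.array(["MI", "Rest"] * (n // 2))
        outcomes = np.array((["hit", "hit", "miss", "miss"]) * (n // 4))
        mats = rng.random((n, 3, 3))
        mats[(conditions == "MI") & (outcomes == "hit")] += effect
        return atm_set(mats, conditions, outcomes)

    def test_swapping_outcome_labels_flips_statistic_sign(self):
        s = self._labeled_set(seed=3, effect=0.4)
        res = ab.hit_miss_contrast(s, n_permutations=50, rng_seed=0)
        swapped = atm_set(
            s.matrices,
            s.condition_labels,
            np.where(s.outcome_labels == "hit", "miss", "hit"),
        )
        res_sw = ab.hit_miss_contrast(swapped, n_permutations=50, rng_seed=0)
        np.testing.assert_allclose(res_sw.statistic, -res.statistic, atol=1e-12)

    def test_planted_hit_effect_detected(self):
        res = ab.hit_miss_contrast(self._labeled_set(seed=4, effect=0.6),
                                   n_permutations=500, rng_seed=1)
        assert res.mean_statistic > 0
        assert res.p_mean < 0.01

    def test_null_statistic_centered(self):
        ps = [
            ab.hit_miss_contrast(self._labeled_set(seed=s), n_permutations=200,
                                 rng_seed=s).p_mean
            for s in range(10)
        ]
        assert min(ps) > 1 / 201  # no spurious floor hits
        assert 0.2 < np.mean(ps) < 0.8

    def test_empty_cell_skipped_with_warning(self):
        s = self._labeled_set(seed=5)
        s.outcome_labels[s.condition_labels == "MI"] = "hit"
        with pytest.warns(UserWarning, match="empty"):
            assert ab.hit_miss_contrast(s, n_permutations=10) is None


class TestBCICorrelation:
    @staticmethod
    def _areas(n_regions=20):
        names = ["executive", "pre/motor", "parietal", "temporal", "occipital"]
        return np.array([names[k % 5] for k in range(n_regions)])

    def test_emits_exactly_25_blocks_for_five_areas(self):
        rng = np.random.default_rng(0)
        res = ab.bci_correlation(
            rng.normal(size=(6, 20, 20)), rng.random(6), self._areas(),
            n_permutations=100, rng_seed=0,
        )
        assert res.block_means.shape == (5, 5)
        assert res.block_p.shape == (5, 5)
        assert res.block_p.size == 25

    def test_planted_block_detected_with_positive_mean(self):
        rng = np.random.default_rng(1)
        n_sub, n_regions = 16, 20
        scores = rng.random(n_sub)
        diffs = 0.3 * rng.normal(size=(n_sub, n_regions, n_regions))
        areas = self._areas(n_regions)
        src = areas == "pre/motor"
        dst = areas == "parietal"
        diffs[:, np.ix_(src, dst)[0], np.ix_(src, dst)[1]] += scores[:, None, None]
        res = ab.bci_correlation(diffs, scores, areas, n_permutations=2000, rng_seed=2)
        i = res.area_names.index("pre/motor")
        j = res.area_names.index("parietal")
        assert res.significant[i, j]
        assert res.block_means[i, j] > 0

    def test_noise_only_scores_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            res = ab.bci_correlation(
                rng.normal(size=(8, 10, 10)), rng.random(8), self._areas(10),
                n_permutations=200, rng_seed=seed,
            )
            hits += res.significant.any()
        assert hits <= 2

    def test_constant_scores_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="constant"):
            ab.bci_correlation(rng.normal(size=(5, 10, 10)), np.full(5, 0.7),
                               self._areas(10), n_permutations=10)

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match=">= 4 subjects"):
            ab.bci_correlation(rng.normal(size=(3, 10, 10)), rng.random(3),
                               self._areas(10), n_permutations=10)
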