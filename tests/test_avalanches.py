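"""Core measurement chain: binarization, segmentation, ATMs, branching ratio."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import avalanchebci as ab
from avalanchebci.avalanches import (
    Avalanche,
    BinaryRaster,
    ZeroVarianceError,
    pooled_atm,
    transition_counts,
)

from conftest import epochs


def raster_from_array(arr, threshold=3.0, bin_length=1):
    return BinaryRaster(
        active=np.asarray(arr, dtype=bool),
        threshold_z=threshold,
        bin_length_samples=bin_length,
    )


class TestBinarize:
    def test_constant_region_raises_named_error(self):
        sig = np.random.default_rng(0).normal(size=(2, 3, 50))
        sig[1, 2] = 4.2
        with pytest.raises(ZeroVarianceError, match="region 2.*trial 1"):
            ab.binarize(epochs(sig, ["MI", "Rest"]))

    def test_gaussian_noise_crossing_rate_matches_normal_tail(self):
        # |z| > 3 on iid normal data: expected rate 2 * (1 - Phi(3))
        rng = np.random.default_rng(42)
        n = 200_000
        data = epochs(rng.normal(size=(1, 1, n)), ["MI"])
        raster = ab.binarize(data, threshold_z=3.0, bin_length_samples=1)
        expected = 2 * (1 - norm.cdf(3.0))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(raster.active.mean() - expected) < 3 * sd

    def test_forced_crossing_is_active(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(1, 2, 400))
        sig[0, 0, 123] = 10 * sig[0, 0].std()
        raster = ab.binarize(epochs(sig, ["MI"]), threshold_z=3.0)
        assert raster.active[0, 0, 123]

    def test_binning_ors_samples(self):
        rng = np.random.default_rng(2)
        sig = 0.01 * rng.normal(size=(1, 1, 30))
        sig[0, 0, 4] = 100.0  # sample 4 -> bin 1 of length 3
        raster = ab.binarize(epochs(sig, ["MI"]), threshold_z=3.0, bin_length_samples=3)
        assert raster.n_bins == 10
        assert raster.active[0, 0, 1]
        assert raster.active[0, 0].sum() == 1

    @pytest.mark.parametrize("bad", [0, -1.0])
    def test_nonpositive_threshold_rejected(self, bad):
        sig = np.random.default_rng(0).normal(size=(1, 2, 30))
        with pytest.raises(ValueError):
            ab.binarize(epochs(sig, ["MI"]), threshold_z=bad)


class TestSegmentation:
    def test_hand_segmented_runs(self):
        act = np.zeros((1, 2, 12), dtype=bool)
        act[0, 0, [2, 3]] = True
        act[0, 1, [4, 7, 8]] = True  # activity bins {2,3,4} and {7,8}
        avs = ab.segment_avalanches(raster_from_array(act))
        assert [(a.start_bin, a.end_bin, a.duration_bins) for a in avs] == [
            (2, 4, 3),
            (7, 8, 2),
        ]
        assert not any(a.truncated_start or a.truncated_end for a in avs)

    def test_all_zero_raster_yields_no_avalanches(self):
        assert ab.segment_avalanches(raster_from_array(np.zeros((2, 3, 8)))) == []

    def test_fully_active_trial_is_one_truncated_avalanche(self):
        avs = ab.segment_avalanches(raster_from_array(np.ones((1, 2, 6))))
        assert len(avs) == 1
        assert avs[0].duration_bins == 6
        assert avs[0].truncated_start and avs[0].truncated_end

    def test_trials_segmented_independently(self):
        act = np.zeros((2, 1, 4), dtype=bool)
        act[0, 0, 3] = True
        act[1, 0, 0] = True  # abutting trial boundary, not merged across trials
        avs = ab.segment_avalanches(raster_from_array(act))
        assert len(avs) == 2
        assert {a.trial_index for a in avs} == {0, 1}

    @given(st.integers(0, 2**40 - 1))
    def test_binning_monotonicity(self, bits):
        # coarser bins merge runs: avalanche count is non-increasing in bin length
        samples = np.array([(bits >> k) & 1 for k in range(40)], dtype=bool)
        counts = []
        for bl in (1, 2, 3):
            n = 40 // bl
            binned = samples[: n * bl].reshape(n, bl).any(axis=1)
            counts.append(
                len(ab.segment_avalanches(raster_from_array(binned[None, None, :], bin_length=bl)))
            )
        assert counts[0] >= counts[1] >= counts[2]


def make_avalanche(active_sets, trial=0, start=0):
    return Avalanche(
        trial_index=trial,
        start_bin=start,
        end_bin=start + len(active_sets) - 1,
        active_sets=[np.asarray(s, dtype=int) for s in active_sets],
    )


def atm_oracle(frames, n_regions):
    """Exhaustive frame-count oracle for the per-avalanche ATM."""
    num = np.zeros((n_regions, n_regions))
    den = np.zeros(n_regions)
    for t in range(len(frames) - 1):
        for i in range(n_regions):
            if frames[t][i]:
                den[i] += 1
                for j in range(n_regions):
                    if frames[t + 1][j]:
                        num[i, j] += 1
    out = np.zeros((n_regions, n_regions))
    for i in range(n_regions):
        if den[i]:
            out[i] = num[i] / den[i]
    return out


class TestTransitionMatrix:
    def test_hand_example_three_regions(self):
        # bins: {A}, {B}, {B, C}
        atm = ab.transition_matrix(make_avalanche([[0], [1], [1, 2]]), 3)
        expected = np.array([[0, 1, 0], [0, 1, 1], [0, 0, 0]], dtype=float)
        np.testing.assert_array_equal(atm.probabilities, expected)

    def test_self_persistence_probability_one(self):
        atm = ab.transition_matrix(make_avalanche([[0], [0]]), 2)
        assert atm.probabilities[0, 0] == 1.0

    def test_last_bin_only_region_has_zero_row(self):
        atm = ab.transition_matrix(make_avalanche([[0], [0, 1]]), 2)
        np.testing.assert_array_equal(atm.probabilities[1], [0.0, 0.0])

    def test_single_bin_avalanche_returns_none(self):
        assert ab.transition_matrix(make_avalanche([[0, 1]]), 2) is None

    @given(
        st.integers(2, 5).flatmap(
            lambda r: st.lists(
                st.lists(st.integers(0, r - 1), min_size=1, max_size=r, unique=True),
                min_size=2,
                max_size=8,
            ).map(lambda sets: (r, sets))
        )
    )
    def test_matches_exhaustive_frame_count_oracle(self, case):
        n_regions, sets = case
        atm = ab.transition_matrix(make_avalanche(sets), n_regions)
        frames = np.zeros((len(sets), n_regions), dtype=bool)
        for t, s in enumerate(sets):
            frames[t, s] = True
        np.testing.assert_allclose(atm.probabilities, atm_oracle(frames, n_regions), atol=0)

    def test_probabilities_within_unit_interval(self, small_cohort):
        atms = ab.extract_trial_atms(small_cohort.subjects[0].data)
        assert atms.matrices.min() >= 0 and atms.matrices.max() <= 1


class TestAveraging:
    def test_single_matrix_is_identity_operation(self):
        atm = ab.transition_matrix(make_avalanche([[0], [1]]), 2)
        avg = ab.average_atm([atm])
        np.testing.assert_array_equal(avg.probabilities, atm.probabilities)

    def test_mean_of_zero_and_one(self):
        a = ab.transition_matrix(make_avalanche([[0], [1]]), 2)  # (0,1) = 1
        b = ab.transition_matrix(make_avalanche([[0], [0]]), 2)  # (0,1) = 0
        avg = ab.average_atm([a, b])
        assert avg.probabilities[0, 1] == 0.5
        assert avg.n_avalanches_averaged == 2

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ab.average_atm([])

    def test_pooled_counts_recover_generating_probability(self):
        # deterministic two-region relay: A -> B with probability 1
        rng = np.random.default_rng(0)
        avs = []
        for _ in range(300):
            dur = rng.integers(2, 5)
            avs.append(make_avalanche([[0] if t % 2 == 0 else [1] for t in range(dur)]))
        pooled = pooled_atm(avs, 2)
        assert pooled.probabilities[0, 1] == 1.0
        assert pooled.probabilities[0, 0] == 0.0


class TestBranchingRatio:
    def test_event_counts_1_2_4_give_sigma_two(self):
        av = make_avalanche([[0], [0, 1], [0, 1, 2, 3]])
        est = ab.branching_ratio([av])
        assert est.sigma == pytest.approx(2.0)

    def test_geometric_mean_of_reciprocal_sigmas_is_one(self):
        doubling = make_avalanche([[0], [0, 1], [0, 1, 2, 3]])  # sigma 2
        halving = make_avalanche([[0, 1, 2, 3], [0, 1], [0]])  # sigma 0.5
        est = ab.branching_ratio([doubling, halving])
        assert est.sigma == pytest.approx(1.0)
        assert est.n_avalanches_used == 2

    def test_deterministic_doubling_cascade_exact(self):
        sets = [list(range(2**k)) for k in range(5)]  # 1, 2, 4, 8, 16 events
        est = ab.branching_ratio([make_avalanche(sets)])
        assert est.sigma == pytest.approx(2.0)

    def test_single_bin_avalanches_excluded_and_counted(self):
        multi = make_avalanche([[0], [1]])
        single = make_avalanche([[0]])
        est = ab.branching_ratio([multi, single, single])
        assert est.n_avalanches_used == 1
        assert est.n_single_bin_excluded == 2
        with pytest.raises(ValueError, match="branching ratio undefined"):
            ab.branching_ratio([single])


class TestExtractTrialATMs:
    def test_identical_trials_give_identical_atms(self):
        rng = np.random.default_rng(3)
        one = rng.normal(size=(1, 4, 200))
        one[0, :, 50:53] += 30
        sig = np.repeat(one, 3, axis=0)
        atms = ab.extract_trial_atms(epochs(sig, ["MI", "Rest", "MI"]))
        np.testing.assert_array_equal(atms.matrices[0], atms.matrices[1])
        np.testing.assert_array_equal(atms.matrices[0], atms.matrices[2])

    def test_trials_without_avalanches_flagged_and_zero(self):
        rng = np.random.default_rng(4)
        sig = rng.normal(size=(2, 3, 300))
        sig[0, 1, 100:105] += 50  # only trial 0 has a (multi-bin) avalanche
        sig[1] = np.clip(sig[1], -2.5, 2.5)  # trial 1: no threshold crossing
        atms = ab.extract_trial_atms(epochs(sig, ["MI", "Rest"]))
        assert atms.has_avalanches[0]
        assert not atms.has_avalanches[1]
        np.testing.assert_array_equal(atms.matrices[1], 0.0)

    def test_region_permutation_equivariance(self, small_cohort):
        data = small_cohort.subjects[0].data
        perm = np.random.default_rng(9).permutation(data.n_regions)
        permuted = epochs(
            data.signals[:, perm, :], data.condition_labels, data.outcome_labels
        )
        base = ab.extract_trial_atms(data).matrices
        shuffled = ab.extract_trial_atms(permuted).matrices
        np.testing.assert_allclose(shuffled, base[:, perm][:, :, perm], atol=1e-12)

    def test_pooled_and_averaged_modes_agree_with_object_route(self, small_cohort):
        from avalanchebci.avalanches import binarize, segment_avalanches, transition_matrix

        data = small_cohort.subjects[1].data
        raster = binarize(data)
        avs = segment_avalanches(raster)
        for pooled in (True, False):
            atms = ab.extract_trial_atms(data, pooled=pooled)
            for trial in range(3):
                multi = [a for a in avs if a.trial_index == trial and a.duration_bins >= 2]
                if not multi:
                    continue
                if pooled:
                    ref = pooled_atm(multi, data.n_regions).probabilities
                else:
                    ref = ab.average_atm(
                        [transition_matrix(a, data.n_regions) for a in multi]
                    ).probabilities
                np.testing.assert_allclose(atms.matrices[trial], ref, atol=1e-12)

    def test_transition_counts_additive(self):
        av = make_avalanche([[0, 1], [1], [0]])
        num, den = transition_counts(av, 3)
        assert den.tolist() == [1.0, 2.0, 0.0]
        assert num[0, 1] == 1.0 and num[1, 0] == 1.0 and num[1, 1] == 1.0
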