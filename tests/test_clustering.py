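"""Event-frame clustering: sampling, Lin's concordance, k-means, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from eventspan.clustering import (
    FrameBank,
    align_models,
    kmeans_fit,
    lins_ccc,
    relative_frequency,
    sample_subjects,
    similarity_curve,
    subsample_frames,
)


def _bank(frames, sids=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    sids = np.asarray(sids) if sids is not None else np.array([f"s{i}" for i in range(n)])
    return FrameBank(
        frames=frames,
        subject_ids=sids,
        age_bin_ids=np.zeros(n, dtype=int),
        frame_indices=np.arange(n),
    )


class TestSampling:
    def _cohort(self, sizes):
        rows = []
        i = 0
        for b, size in enumerate(sizes):
            for _ in range(size):
                rows.append({"subject": f"s{i}", "age_bin": b})
                i += 1
        return pd.DataFrame(rows)

    def test_single_member_bin_is_forced(self):
        out = sample_subjects(self._cohort([1]), 20, seed=0)
        assert out == ["s0"] * 20

    def test_total_draws(self):
        out = sample_subjects(self._cohort([5] * 7), 20, seed=0)
        assert len(out) == 140

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sample_subjects(pd.DataFrame({"subject": [], "age_bin": []}), 5, seed=0)

    def test_expected_sample_overlap_below_half(self):
        """With-replacement samples of 20 from a 40-strong bin overlap < 50%."""
        cohort = self._cohort([40])
        rng = np.random.default_rng(0)
        overlaps = []
        for _ in range(300):
            a = set(sample_subjects(cohort, 20, rng))
            b = set(sample_subjects(cohort, 20, rng))
            overlaps.append(len(a & b) / 20.0)
        assert np.mean(overlaps) < 0.5


class TestSubsampleFrames:
    def test_keeps_all_when_fewer_than_k(self, rng):
        bank = subsample_frames({"a": rng.standard_normal((3, 10))}, k=10, seed=0)
        assert bank.n_events == 3

    def test_caps_at_k(self, rng):
        bank = subsample_frames({"a": rng.standard_normal((30, 10))}, k=10, seed=0)
        assert bank.n_events == 10

    def test_deterministic(self, rng):
        ev = {"a": rng.standard_normal((30, 10))}
        a = subsample_frames(ev, k=5, seed=3)
        b = subsample_frames(ev, k=5, seed=3)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_zero_event_subject_skipped(self, rng, caplog):
        ev = {"a": np.empty((0, 10)), "b": rng.standard_normal((4, 10))}
        bank = subsample_frames(ev, k=5, seed=0)
        assert set(bank.subject_ids) == {"b"}


class TestLinsCCC:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert lins_ccc(x, x) == pytest.approx(1.0)

    def test_perfect_anticoncordance(self):
        assert lins_ccc(np.array([-1.0, 1.0]), np.array([1.0, -1.0])) == pytest.approx(-1.0)

    def test_shifted_line_hand_value(self):
        # identical shapes offset by 1: rho_c = 4/7 although Pearson r = 1
        assert lins_ccc(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])) == pytest.approx(4 / 7)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            lins_ccc(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_magnitude_never_exceeds_pearson(self, rng):
        for _ in range(1000):
            x = rng.standard_normal(20) * rng.uniform(0.5, 3)
            y = rng.standard_normal(20) + rng.uniform(-2, 2)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lins_ccc(x, y)) <= abs(r) + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30),
        st.floats(0.1, 10),
        st.floats(-100, 100),
        st.integers(0, 2**31 - 1),
    )
    def test_concordance_properties(self, xs, scale, shift, seed):
        """|rho_c| <= |r| always; equality under identical mean and variance;
        rho_c(x, x) = 1 for any non-constant x."""
        x = np.asarray(xs)
        if np.std(x) < 1e-6:
            return
        y = scale * np.random.default_rng(seed).permutation(x) + shift
        r = np.corrcoef(x, y)[0, 1]
        assert abs(lins_ccc(x, y)) <= abs(r) + 1e-9
        assert lins_ccc(x, x) == pytest.approx(1.0)


class TestKMeans:
    def _planted(self, rng, n_per=40, n_dim=300, noise=0.5):
        a = rng.standard_normal(n_dim)
        b = rng.standard_normal(n_dim)
        frames = np.vstack(
            [a + noise * rng.standard_normal((n_per, n_dim)),
             b + noise * rng.standard_normal((n_per, n_dim))]
        )
        labels = np.repeat([0, 1], n_per)
        return _bank(frames), labels

    @pytest.mark.parametrize("metric", ["pearson", "lins_ccc"])
    def test_recovers_planted_two_clusters(self, rng, metric):
        bank, truth = self._planted(rng)
        model = kmeans_fit(bank, K=2, metric=metric, seed=1)
        assert adjusted_rand_score(truth, model.labels) >= 0.9

    def test_k1_centroid_is_grand_mean(self, rng):
        bank = _bank(rng.standard_normal((10, 50)))
        model = kmeans_fit(bank, K=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], bank.frames.mean(axis=0))

    def test_k_equals_n_forces_singletons(self, rng):
        bank = _bank(rng.standard_normal((4, 30)))
        model = kmeans_fit(bank, K=4, seed=0)
        assert len(np.unique(model.labels)) == 4
        np.testing.assert_allclose(model.mean_within_similarity, 1.0)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(_bank(rng.standard_normal((3, 10))), K=5, seed=0)

    def test_centroid_fixed_point(self, rng):
        bank, _ = self._planted(rng)
        model = kmeans_fit(bank, K=2, seed=2)
        for k in range(2):
            recomputed = bank.frames[model.labels == k + 1].mean(axis=0)
            np.testing.assert_allclose(model.centroids[k], recomputed, atol=1e-12)


class TestAlignment:
    def test_swapped_labels_recovered_at_zero_cost(self, rng):
        bank, _ = self._mk(rng)
        m1 = kmeans_fit(bank, K=2, seed=0)
        m2 = kmeans_fit(bank, K=2, seed=5)
        aligned, ref = align_models([m1, m2])
        c = np.corrcoef(aligned[0].centroids[0], aligned[1].centroids[0])[0, 1]
        assert c > 0.99

    def _mk(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        frames = np.vstack([a + 0.3 * rng.standard_normal((20, 200)),
                            b + 0.3 * rng.standard_normal((20, 200))])
        return _bank(frames), None

    def test_self_alignment_is_identity(self, rng):
        bank, _ = self._mk(rng)
        m = kmeans_fit(bank, K=2, seed=0)
        aligned, _ = align_models([m])
        np.testing.assert_array_equal(aligned[0].labels, m.labels)

    def test_mismatched_k_rejected(self, rng):
        bank, _ = self._mk(rng)
        with pytest.raises(ValueError):
            align_models([kmeans_fit(bank, K=2, seed=0), kmeans_fit(bank, K=3, seed=0)])

    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    def test_assignment_cost_matches_exhaustive_minimum(self, rng, K):
        """Hungarian alignment equals brute force over all K! permutations."""
        from itertools import permutations

        from eventspan.clustering import _centroid_cost
        from scipy.optimize import linear_sum_assignment

        for _ in range(20):
            a = rng.standard_normal((K, 40))
            b = rng.standard_normal((K, 40))
            cost = _centroid_cost(a, b)
            rows, cols = linear_sum_assignment(cost)
            lsa = cost[rows, cols].sum()
            brute = min(
                sum(cost[i, p[i]] for i in range(K)) for p in permutations(range(K))
            )
            assert lsa == pytest.approx(brute, abs=1e-12)


class TestSimilarityCurve:
    def test_identical_banks_give_unit_similarity(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        frames = np.vstack([a + 0.1 * rng.standard_normal((15, 100)),
                            b + 0.1 * rng.standard_normal((15, 100))])
        bank = _bank(frames)
        models = {2: [kmeans_fit(bank, K=2, seed=s) for s in range(3)]}
        curve = similarity_curve(models)
        assert curve.loc[0, "mean_similarity"] == pytest.approx(1.0, abs=1e-6)

    def test_single_repetition_rejected(self, rng):
        bank = _bank(rng.standard_normal((10, 30)))
        with pytest.raises(ValueError):
            similarity_curve({2: [kmeans_fit(bank, K=2, seed=0)]})


class TestRelativeFrequency:
    def test_counts_over_valid_frames(self):
        out = relative_frequency(
            {"a": np.array([1] * 5 + [2] * 5)}, {"a": 1000}, K=2
        )
        assert out.loc[0, "rate_1"] == pytest.approx(0.005)
        assert out.loc[0, "rate_2"] == pytest.approx(0.005)

    def test_no_events_gives_zero_rates(self):
        out = relative_frequency({"a": np.array([], dtype=int)}, {"a": 500}, K=2)
        assert out.loc[0, "rate_1"] == 0.0 and out.loc[0, "rate_2"] == 0.0

    def test_zero_valid_frames_rejected(self):
        with pytest.raises(ValueError):
            relative_frequency({"a": np.array([1])}, {"a": 0}, K=2)
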