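import numpy as np
import pytest

from afterimage import decoding, synthetic
from afterimage.decoding import (
    UNCLASSIFIABLE,
    decoding_significance,
    iti_decoding,
    knn_predict_loto,
    session_accuracy_vs_chance,
    timecourse_decoding,
)
from afterimage.session import WindowSpec

ITI_20 = WindowSpec("ITI", 0.0, 20.0, "odor_offset")
ON_4 = WindowSpec("ON", 0.0, 4.0, "odor_onset")


def _brute_force_knn(X, trial_ids, labels, k, metric):
    """Independent oracle: python loops, explicit distances, explicit
    leave-one-trial-out exclusion and nearest-member tie-break."""
    preds = []
    for i in range(len(X)):
        cand = []
        for j in range(len(X)):
            if trial_ids[j] == trial_ids[i]:
                continue
            if metric == "correlation":
                xc = X[i] - X[i].mean()
                yc = X[j] - X[j].mean()
                denom = np.linalg.norm(xc) * np.linalg.norm(yc)
                if denom == 0:
                    continue
                d = 1.0 - float(xc @ yc) / denom
            else:
                denom = np.linalg.norm(X[i]) * np.linalg.norm(X[j])
                if denom == 0:
                    continue
                d = np.degrees(np.arccos(np.clip(
                    float(X[i] @ X[j]) / denom, -1, 1)))
            cand.append((d, j))
        cand.sort(key=lambda t: (t[0], t[1]))
        near = cand[:k]
        if not near:
            preds.append(UNCLASSIFIABLE)
            continue
        counts = {}
        for _, j in near:
            counts[labels[j]] = counts.get(labels[j], 0) + 1
        top = max(counts.values())
        tied = {l for l, c in counts.items() if c == top}
        for _, j in near:  # nearest member of a tied label wins
            if labels[j] in tied:
                preds.append(labels[j])
                break
    return np.array(preds)


class TestKnnLoto:
    def test_noiseless_two_clusters_k1(self):
        X = np.array([[1.0, 0, 0]] * 4 + [[0, 1.0, 0]] * 4)
        X = X + 0.01 * np.arange(8)[:, None]  # break exact ties
        trials = np.arange(8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        preds = knn_predict_loto(X, trials, labels, k=1, metric="angular")
        np.testing.assert_array_equal(preds, labels)

    @pytest.mark.parametrize("metric", ["correlation", "angular"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, metric, seed):
        rng = np.random.default_rng(seed)
        n = 24
        X = rng.random((n, 6)) + 0.2
        trials = rng.integers(0, 8, size=n)
        labels = np.array(list("abc"))[rng.integers(0, 3, size=n)]
        preds = knn_predict_loto(X, trials, labels, k=3, metric=metric)
        oracle = _brute_force_knn(X, trials, labels, 3, metric)
        np.testing.assert_array_equal(preds, oracle)

    def test_six_point_hand_instance(self):
        X = np.array([[1.0, 0.0], [0.9, 0.1], [0.8, 0.0],
                      [0.0, 1.0], [0.1, 0.9], [0.0, 0.8]])
        trials = np.array([0, 1, 2, 3, 4, 5])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        preds = knn_predict_loto(X, trials, labels, k=3, metric="angular")
        np.testing.assert_array_equal(
            preds, _brute_force_knn(X, trials, labels, 3, "angular"))
        np.testing.assert_array_equal(preds, labels)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        n = 1000
        X = rng.random((n, 8))
        trials = np.arange(n)
        labels = np.array(["a", "b"])[rng.integers(0, 2, size=n)]
        preds = knn_predict_loto(X, trials, labels, k=5)
        acc = (preds == labels).mean()
        assert abs(acc - 0.5) < 0.05

    def test_no_neighbor_from_own_trial(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 5))
        trials = np.repeat(np.arange(6), 5)
        neigh = decoding._neighbor_table(X, trials, k=4, metric="correlation")
        for i in range(30):
            assert all(trials[j] != trials[i] for j in neigh[i] if j >= 0)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.random((20, 4))
        trials = np.arange(20)
        labels = np.array(list("ab"))[rng.integers(0, 2, 20)]
        mapping = {"a": "x", "b": "y"}
        renamed = np.array([mapping[l] for l in labels])
        acc1 = (knn_predict_loto(X, trials, labels, k=3) == labels).mean()
        acc2 = (knn_predict_loto(X, trials, renamed, k=3) == renamed).mean()
        assert acc1 == acc2

    def test_correlation_metric_affine_invariant(self):
        rng = np.random.default_rng(12)
        X = rng.random((16, 6))
        trials = np.arange(16)
        labels = np.array(list("ab"))[rng.integers(0, 2, 16)]
        scales = rng.uniform(0.5, 3.0, size=(16, 1))
        shifts = rng.uniform(-2, 2, size=(16, 1))
        p1 = knn_predict_loto(X, trials, labels, k=3, metric="correlation")
        p2 = knn_predict_loto(scales * X + shifts, trials, labels, k=3,
                              metric="correlation")
        np.testing.assert_array_equal(p1, p2)

    def test_angular_metric_scale_invariant(self):
        rng = np.random.default_rng(13)
        X = rng.random((16, 6)) + 0.1
        trials = np.arange(16)
        labels = np.array(list("ab"))[rng.integers(0, 2, 16)]
        scales = rng.uniform(0.5, 3.0, size=(16, 1))
        p1 = knn_predict_loto(X, trials, labels, k=3, metric="angular")
        p2 = knn_predict_loto(scales * X, trials, labels, k=3,
                              metric="angular")
        np.testing.assert_array_equal(p1, p2)

    def test_zero_variance_query_unclassifiable(self):
        X = np.vstack([np.ones(4), np.random.default_rng(0).random((5, 4))])
        trials = np.arange(6)
        labels = np.array(list("ababab"))
        preds = knn_predict_loto(X, trials, labels, k=2, metric="correlation")
        assert preds[0] == UNCLASSIFIABLE

    def test_parameter_errors(self):
        X = np.random.default_rng(0).random((6, 3))
        with pytest.raises(ValueError, match="k"):
            knn_predict_loto(X, np.arange(6), np.array(list("aabbcc")), k=0)
        with pytest.raises(ValueError, match="metric"):
            knn_predict_loto(X, np.arange(6), np.array(list("aabbcc")),
                             k=1, metric="euclidean")
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict_loto(X, np.arange(6), np.array(list("aabbcc")), k=9)


class TestSessionDecoding:
    def test_locust_pool_bookkeeping(self, locust_session):
        sess, _ = locust_session
        iti21 = WindowSpec("ITI", 0.0, 21.0, "odor_offset")
        X, labels, trials, bins, _ = decoding._pool_vectors(
            sess, iti21, 0.2, None, average=False)
        # 4 odors x 10 trials x 105 bins of 200 ms over the 21 s ITI
        assert len(X) == 4 * 10 * 105
        assert bins.max() == 104

    def test_high_snr_on_period_near_perfect(self, locust_session):
        sess, _ = locust_session
        res = timecourse_decoding(sess, ON_4, bin_width_s=0.2, k=10)
        assert np.nanmean(res.overall_accuracy) > 0.95
        assert res.chance == pytest.approx(0.25)

    def test_iti_averaged_one_vector_per_trial(self, locust_session):
        sess, _ = locust_session
        res = iti_decoding(sess, ITI_20, k=10)
        assert res.n_vectors == len(sess.trials)
        assert res.overall_accuracy[0] > 0.9  # strong hysteresis default

    def test_no_iti_signal_near_chance(self):
        cfg = synthetic.locust_like(
            odors=("a", "b", "c", "d"), iti_s=24.0, seed=5,
            hysteresis_eta=0.0, tau_off_s=1.0)
        sess, _ = synthetic.generate_session(cfg)
        late_iti = WindowSpec("ITI", 8.0, 20.0, "odor_offset")
        res = iti_decoding(sess, late_iti, k=10)
        res = decoding_significance(res, n_perm=300, seed=1)
        # within the spread of the permutation null around chance
        null_sd = 0.0
        null_sd = max(null_sd, float(res.null_band[1, 0] - res.null_mean[0]))
        assert abs(res.overall_accuracy[0] - res.null_mean[0]) <= null_sd


class TestSignificance:
    def test_perfectly_decodable_all_bins_significant(self, locust_session):
        sess, _ = locust_session
        res = timecourse_decoding(sess, ON_4, bin_width_s=0.5, k=10)
        res = decoding_significance(res, n_perm=200, seed=3)
        assert res.significant_bins.all()
        np.testing.assert_allclose(res.p_values, 1 / 201)

    def test_seeded_masks_reproducible(self, locust_session):
        sess, _ = locust_session
        res = timecourse_decoding(sess, ON_4, bin_width_s=0.5, k=10)
        a = decoding_significance(res, n_perm=100, seed=7)
        b = decoding_significance(res, n_perm=100, seed=7)
        np.testing.assert_array_equal(a.significant_bins, b.significant_bins)
        np.testing.assert_allclose(a.null_mean, b.null_mean)

    def test_random_labels_fdr_controlled(self):
        rng = np.random.default_rng(21)
        from afterimage.session import RecordingSession, TrialRecord

        trials = []
        for i in range(24):
            t0 = 30.0 * i
            trials.append(TrialRecord(
                trial_id=f"t{i}", odor="abcd"[i % 4], t_start_s=t0,
                t_end_s=t0 + 28.0,
                odor_sequence=[("abcd"[i % 4], t0 + 2.0, t0 + 6.0)],
                activity={f"u{u}": np.sort(t0 + 28.0 * rng.random(60))
                          for u in range(12)}))
        sess = RecordingSession("spikes", [f"u{u}" for u in range(12)], trials)
        res = timecourse_decoding(sess, ITI_20, bin_width_s=1.0, k=5)
        res = decoding_significance(res, n_perm=200, seed=2)
        # labels carry no information: at most ~q of bins may come up
        assert res.significant_bins.mean() <= 0.1

    def test_too_few_permutations_rejected(self, locust_session):
        sess, _ = locust_session
        res = timecourse_decoding(sess, ON_4, bin_width_s=1.0, k=10)
        with pytest.raises(ValueError):
            decoding_significance(res, n_perm=10)


class TestAccuracyVsChance:
    def test_chance_11_odors(self):
        assert round(100 / 11, 1) == 9.1

    def test_sessions_at_chance_nothing_significant(self):
        rng = np.random.default_rng(30)
        A = 0.25 + 0.01 * rng.standard_normal((6, 50))
        res = session_accuracy_vs_chance(A, chance=0.25, bin_group=5)
        assert res.significant.sum() == 0

    def test_sessions_above_chance_all_significant(self):
        rng = np.random.default_rng(31)
        A = 0.45 + 0.01 * rng.standard_normal((6, 50))
        res = session_accuracy_vs_chance(A, chance=0.25, bin_group=5)
        assert res.significant.all()
        assert len(res.p_values) == 10  # 50 bins grouped by 5

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            session_accuracy_vs_chance(np.zeros((1, 20)), chance=0.1)
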