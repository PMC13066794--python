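import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from afterimage import geometry, preprocess
from afterimage.geometry import (
    angle_between,
    angle_distributions,
    cluster_angular,
    linkage_to_newick,
    pca_trajectory,
    pearson,
    period_correlation,
    random_vector_null,
    reference_angles,
    timebin_correlation,
)
from afterimage.preprocess import BinnedResponse
from afterimage.session import WindowSpec

ON_W = WindowSpec("ON", 0.0, 4.0, "odor_onset")
OFF_W = WindowSpec("OFF", 0.0, 4.0, "odor_offset")


def _binned(values, window="ON", subtracted=True):
    values = np.asarray(values, float)
    edges = 0.05 * np.arange(values.shape[0] + 1)
    units = [f"u{i}" for i in range(values.shape[1])]
    return BinnedResponse(values, edges, units, "hex", window, "t0",
                          baseline_subtracted=subtracted)


class TestTimebinCorrelation:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        b = _binned(rng.random((6, 5)))
        C = timebin_correlation(b, b)
        np.testing.assert_allclose(np.diag(C.values), 1.0)

    def test_perfect_anticorrelation(self):
        row = np.array([1.0, 2.0, 5.0, 3.0])
        b = _binned(np.vstack([row, 10.0 - 2.0 * row]))
        C = timebin_correlation(b, b)
        assert C.values[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_pearson(self):
        rng = np.random.default_rng(1)
        A, B = _binned(rng.random((5, 4))), _binned(rng.random((3, 4)), "OFF")
        C = timebin_correlation(A, B)
        for i in range(5):
            for j in range(3):
                x, y = A.values[i], B.values[j]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert C.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_is_missing_not_zero(self):
        vals = np.array([[1.0, 1.0, 1.0], [0.5, 1.0, 2.0]])
        C = timebin_correlation(_binned(vals), _binned(vals))
        assert np.isnan(C.values[0, 1])
        assert not np.isnan(C.values[1, 1])


class TestPeriodCorrelation:
    def test_identical_vectors_correlate_fully(self):
        v = np.array([1.0, 4.0, 2.0])
        C = period_correlation({("a", "ON"): v, ("b", "ON"): v.copy()})
        assert C.values[0, 1] == pytest.approx(1.0)

    def test_shape_and_symmetry_4_odors(self):
        rng = np.random.default_rng(2)
        vectors = {(o, p): rng.random(6)
                   for o in "wxyz" for p in ("ON", "OFF")}
        C = period_correlation(vectors)
        assert C.values.shape == (8, 8)
        np.testing.assert_allclose(C.values, C.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C.values), 1.0)

    def test_equals_timebin_on_time_averaged_rows(self):
        rng = np.random.default_rng(3)
        va, vb = rng.random(7), rng.random(7)
        C_period = period_correlation({("a", "ON"): va, ("b", "OFF"): vb})
        C_tb = timebin_correlation(_binned(va[None, :]),
                                   _binned(vb[None, :], "OFF"))
        assert C_period.values[0, 1] == pytest.approx(C_tb.values[0, 0])

    def test_anticorrelated_session_has_negative_on_off_block(self,
                                                             locust_session):
        sess, _ = locust_session
        vectors = {}
        for odor in sess.odors:
            on = preprocess.response_matrix(sess, odor, ON_W, bin_width_s=0.05)
            off = preprocess.response_matrix(sess, odor, OFF_W, bin_width_s=0.05)
            vectors[(odor, "ON")] = preprocess.time_average(on)
            vectors[(odor, "OFF")] = preprocess.time_average(off)
        C = period_correlation(vectors)
        idx = {lab: i for i, lab in enumerate(C.row_index)}
        cross = [C.values[idx[(o, "ON")], idx[(o, "OFF")]]
                 for o in sess.odors]
        assert np.mean(cross) < 0


class TestAngles:
    def test_canonical_angles(self):
        v = np.array([1.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0])
        assert angle_between(v, v) == pytest.approx(0.0)
        assert angle_between(v, w) == pytest.approx(90.0)
        assert angle_between(v, -v) == pytest.approx(180.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            angle_between(np.zeros(3), np.ones(3))

    @given(arrays(float, 6, elements=st.floats(-5, 5)),
           arrays(float, 6, elements=st.floats(-5, 5)))
    def test_reflection_identity(self, v, w):
        """angle(v, w) == 180 - angle(v, -w) for all non-zero vectors."""
        if np.linalg.norm(v) < 1e-6 or np.linalg.norm(w) < 1e-6:
            return
        assert angle_between(v, w) == pytest.approx(
            180.0 - angle_between(v, -w), abs=1e-6)

    @given(arrays(float, 8, elements=st.floats(-3, 3)),
           arrays(float, 8, elements=st.floats(-3, 3)))
    def test_negative_pearson_iff_centered_angle_obtuse(self, v, w):
        vc, wc = v - v.mean(), w - w.mean()
        if np.linalg.norm(vc) < 1e-6 or np.linalg.norm(wc) < 1e-6:
            return
        r = pearson(v, w)
        ang = angle_between(vc, wc)
        if abs(r) > 1e-9 and abs(ang - 90.0) > 1e-6:
            assert (r < 0) == (ang > 90.0)

    def test_pair_counts_80_bins(self):
        rng = np.random.default_rng(4)
        on = _binned(rng.random((80, 10)))
        off = _binned(rng.random((80, 10)), "OFF")
        on_on, off_off, on_off = angle_distributions(on, off)
        assert len(on_on.angles_deg) == 3160
        assert len(off_off.angles_deg) == 3160
        assert len(on_off.angles_deg) == 6400

    def test_identical_on_bins_give_zero_angle(self):
        row = np.array([1.0, 2.0, 0.5, 3.0])
        on = _binned(np.vstack([row, row]))
        off = _binned(np.vstack([row, -row]), "OFF")
        on_on, _, _ = angle_distributions(on, off, centering="none")
        np.testing.assert_allclose(on_on.angles_deg, [0.0], atol=1e-5)

    def test_single_bin_period_warns_and_is_empty(self):
        on = _binned(np.array([[1.0, 2.0, 3.0]]))
        off = _binned(np.random.default_rng(0).random((4, 3)), "OFF")
        with pytest.warns(UserWarning, match="too few"):
            on_on, _, _ = angle_distributions(on, off)
        assert len(on_on.angles_deg) == 0


class TestReferenceAngles:
    def test_inclusion_modes(self):
        rng = np.random.default_rng(5)
        vectors = {(o, p): rng.random(9)
                   for o in ("hex", "bza", "oct") for p in ("ON", "OFF")}
        ref_on, ref_off = reference_angles(vectors, "hex",
                                           include_reference=True)
        assert len(ref_on.angles_deg) == 3
        assert len(ref_off.angles_deg) == 3
        assert ref_on.angles_deg.min() == pytest.approx(0.0, abs=1e-6)
        ref_on2, ref_off2 = reference_angles(vectors, "hex",
                                             include_reference=False)
        assert len(ref_on2.angles_deg) == 2
        assert len(ref_off2.angles_deg) == 2


class TestRandomNull:
    def test_median_near_90_and_deterministic(self):
        null = random_vector_null(66, 10_000, rng=7)
        assert null.median() == pytest.approx(90.0, abs=2.0)
        again = random_vector_null(66, 10_000, rng=7)
        np.testing.assert_array_equal(null.angles_deg, again.angles_deg)

    def test_2d_is_broad_with_mean_90(self):
        null = random_vector_null(2, 20_000, rng=8)
        assert np.mean(null.angles_deg) == pytest.approx(90.0, abs=2.0)
        assert np.std(null.angles_deg) > 40.0  # uniform on (0, 180)

    def test_spread_shrinks_with_dimension(self):
        spreads = [np.std(random_vector_null(d, 5000, rng=9).angles_deg)
                   for d in (5, 50, 500)]
        assert spreads[0] > spreads[1] > spreads[2]

    def test_dimension_guard(self):
        with pytest.raises(ValueError):
            random_vector_null(1)


class TestPca:
    def test_planar_data_has_negligible_third_component(self):
        rng = np.random.default_rng(10)
        basis = rng.random((2, 6))
        X = rng.random((40, 2)) @ basis + 1e-9 * rng.random((40, 6))
        _, evr = pca_trajectory(X, n_components=3)
        assert evr[2] == pytest.approx(0.0, abs=1e-12)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(11)
        X = rng.random((30, 5))
        proj, evr = pca_trajectory(X, n_components=3)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        np.testing.assert_allclose(evr, eigvals[:3] / eigvals.sum(),
                                   atol=1e-10)
        # projection preserves the top-3 variance
        np.testing.assert_allclose(proj.var(axis=0, ddof=1), eigvals[:3],
                                   atol=1e-10)

    def test_rank_deficit_warns(self):
        X = np.tile(np.arange(4.0)[:, None], (1, 5))
        with pytest.warns(UserWarning, match="rank"):
            _, evr = pca_trajectory(X, n_components=3)
        assert len(evr) == 1

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(12)
        X = rng.random((20, 6))
        p1, _ = pca_trajectory(X)
        p2, _ = pca_trajectory(X.copy())
        np.testing.assert_allclose(p1, p2)


class TestClustering:
    def test_two_groups_bipartition(self):
        rng = np.random.default_rng(13)
        on_like = {f"on{i}": np.r_[1.0, 0, 0, 0] + 0.05 * rng.random(4)
                   for i in range(3)}
        off_like = {f"off{i}": np.r_[0, 0, 1.0, 0] + 0.05 * rng.random(4)
                    for i in range(3)}
        Z, labels = cluster_angular({**on_like, **off_like}, centering="none")
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(Z, 2, criterion="maxclust")
        groups = {}
        for lab, c in zip(labels, two):
            groups.setdefault(c, set()).add(lab[:2])
        assert sorted(map(tuple, groups.values())) == [("of",), ("on",)]

    def test_merge_order_matches_hand_computation(self):
        # three unit vectors with pairwise angles 30, 60, 90 degrees
        def u(theta):
            return np.array([np.cos(np.radians(theta)),
                             np.sin(np.radians(theta))])
        Z, labels = cluster_angular({"a": u(0), "b": u(30), "c": u(90)},
                                    centering="none")
        # first merge: a-b at 30 deg; then c joins at complete-linkage 90
        assert Z[0, 2] == pytest.approx(30.0, abs=1e-6)
        assert Z[1, 2] == pytest.approx(90.0, abs=1e-6)

    def test_identical_vectors_merge_at_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        Z, _ = cluster_angular({"a": v, "b": v.copy(), "c": v.copy()},
                               centering="none")
        np.testing.assert_allclose(Z[:, 2], 0.0, atol=1e-5)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            cluster_angular({"a": np.ones(3)})  # < 2 vectors

    def test_newick_roundtrip(self):
        def u(theta):
            return np.array([np.cos(np.radians(theta)),
                             np.sin(np.radians(theta))])
        Z, labels = cluster_angular({"a": u(0), "b": u(30), "c": u(90)},
                                    centering="none")
        nwk = linkage_to_newick(Z, labels)
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]
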