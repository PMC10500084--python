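import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scace import (
    apply_merge,
    ari,
    build_merge_plan,
    clustering_kl_loss,
    compute_centroids,
    merge_until_stable,
    network_update,
    soft_assign,
    target_distribution,
)
from scace.cluster_init import ClusterState

from conftest import blob_embedding


def state_from(z, labels):
    labels = np.asarray(labels)
    cents = compute_centroids(z, labels)
    return ClusterState(labels=labels, centroids=cents, K=cents.shape[1])


# ---------------------------------------------------------------------------
# soft assignment / target distribution / clustering loss
# ---------------------------------------------------------------------------


class TestSoftAssign:
    def test_single_cluster_all_ones(self):
        z = np.random.default_rng(0).standard_normal((3, 10))
        q = soft_assign(z, z.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(q, 1.0)

    def test_equidistant_symmetry(self):
        z = np.array([[0.0]])  # one cell at origin (1-D)
        cents = np.array([[-2.0, 2.0]])
        q = soft_assign(z, cents)
        np.testing.assert_allclose(q, [[0.5, 0.5]])

    def test_derived_hand_value(self):
        # dist^2 = 0 and 1 -> kernel (1, 1/2) -> q = (2/3, 1/3)
        z = np.array([[0.0]])
        cents = np.array([[0.0, 1.0]])
        q = soft_assign(z, cents)
        np.testing.assert_allclose(q, [[2.0 / 3.0, 1.0 / 3.0]], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        q = soft_assign(rng.standard_normal((4, 50)), rng.standard_normal((4, 6)))
        np.testing.assert_allclose(q.sum(1), 1.0, atol=1e-12)
        assert np.all((q > 0) & (q < 1))

    def test_non_finite_rejected(self):
        z = np.array([[np.nan]])
        with pytest.raises(ValueError):
            soft_assign(z, np.array([[0.0]]))


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        q = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        np.testing.assert_array_equal(target_distribution(q), q)

    def test_identical_rows_stay_identical(self):
        q = np.tile([[0.3, 0.7]], (5, 1))
        p = target_distribution(q)
        assert np.all(p == p[0])

    def test_derived_hand_value(self):
        q = np.array([[0.8, 0.2], [0.4, 0.6]])
        p = target_distribution(q)
        # f = (1.2, 0.8); row 1: (0.64/1.2, 0.04/0.8) normalized
        f = np.array([1.2, 0.8])
        expected = q**2 / f
        expected /= expected.sum(1, keepdims=True)
        np.testing.assert_allclose(p, expected, atol=1e-12)
        np.testing.assert_allclose(p[0], [0.914286, 0.085714], atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        q = rng.dirichlet(np.ones(5), size=40)
        p = target_distribution(q)
        np.testing.assert_allclose(p.sum(1), 1.0, atol=1e-12)


class TestClusteringKlLoss:
    def test_zero_iff_equal(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet(np.ones(4), size=20)
        assert clustering_kl_loss(q, q) == pytest.approx(0.0, abs=1e-14)

    def test_point_mass_vs_uniform(self):
        p = np.array([[1.0, 0.0]])
        q = np.array([[0.5, 0.5]])
        assert clustering_kl_loss(p, q) == pytest.approx(np.log(2.0), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=10)
        q = rng.dirichlet(np.ones(3), size=10)
        val = clustering_kl_loss(p, q)
        assert val >= -1e-12
        if not np.allclose(p, q):
            assert val > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            clustering_kl_loss(np.ones((2, 2)) / 2, np.ones((3, 2)) / 2)


# ---------------------------------------------------------------------------
# merge plan: brute-force oracle + algebraic properties
# ---------------------------------------------------------------------------


def brute_force_plan(z, labels):
    """Direct double-loop recomputation of the merge quantities (test-only)."""
    zc = z.T  # cells x d
    K = int(labels.max()) + 1
    cents = np.array([zc[labels == k].mean(axis=0) for k in range(K)])
    d_intra = np.array(
        [np.mean([np.linalg.norm(p - cents[k]) for p in zc[labels == k]]) for k in range(K)]
    )
    d_inter = np.zeros((K, K))
    w = np.zeros((K, K))
    mean_intra = d_intra.mean()
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            d_inter[i, j] = np.linalg.norm(cents[i] - cents[j])
            w[i, j] = mean_intra / (0.5 * (d_intra[i] + d_intra[j]))
    acc = 0.0
    for i in range(K):
        for j in range(i + 1, K):
            acc += w[i, j] * d_inter[i, j]
    d_bar = 2.0 / (K * (K - 1)) * acc
    cands = []
    for i in range(K):
        for j in range(i + 1, K):
            wd = w[i, j] * d_inter[i, j]
            if wd < d_bar / 2.0:
                cands.append((i, j, wd))
    selected = min(cands, key=lambda t: (t[2], t[0], t[1]))[:2] if cands else None
    return d_intra, d_inter, w, d_bar, cands, selected


def random_instance(rng, k_max=8, d_max=4):
    K = int(rng.integers(2, k_max + 1))
    d = int(rng.integers(1, d_max + 1))
    sizes = rng.integers(2, 10, size=K)
    centers = rng.standard_normal((K, d)) * rng.uniform(0.5, 5.0)
    pts, labels = [], []
    for k in range(K):
        pts.append(centers[k] + rng.standard_normal((sizes[k], d)) * rng.uniform(0.05, 1.0))
        labels += [k] * sizes[k]
    return np.vstack(pts).T, np.array(labels)


class TestBuildMergePlan:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            z, labels = random_instance(rng)
            state = state_from(z, labels)
            plan = build_merge_plan(z, state)
            di, dj, w, d_bar, cands, selected = brute_force_plan(z, labels)
            np.testing.assert_allclose(plan.d_intra, di, atol=1e-10)
            np.testing.assert_allclose(plan.d_inter, dj, atol=1e-10)
            offdiag = ~np.eye(len(di), dtype=bool)
            np.testing.assert_allclose(plan.w[offdiag], w[offdiag], atol=1e-10)
            assert plan.d_bar == pytest.approx(d_bar, abs=1e-10)
            assert plan.selected_pair == selected
            assert len(plan.candidate_pairs) == len(cands)

    def test_k2_criterion_unsatisfiable(self):
        # with one pair, d_bar equals the pair's weighted distance, which can
        # never be below half of itself
        rng = np.random.default_rng(7)
        for _ in range(1000):
            z, labels = random_instance(rng, k_max=2)
            state = state_from(z, labels)
            plan = build_merge_plan(z, state)
            assert plan.selected_pair is None
            assert plan.candidate_pairs == []

    def test_derived_1d_toy(self):
        # clusters {-0.5, 0.5}, {0.5, 1.5}, {9.5, 10.5}: centroids 0, 1, 10,
        # intra = 0.5 each -> w = 1, d_bar = 20/3, threshold 10/3; only the
        # (0, 1) pair (weighted distance 1) qualifies
        z = np.array([[-0.5, 0.5, 0.5, 1.5, 9.5, 10.5]])
        labels = np.array([0, 0, 1, 1, 2, 2])
        plan = build_merge_plan(z, state_from(z, labels))
        np.testing.assert_allclose(plan.d_intra, 0.5)
        np.testing.assert_allclose(plan.w[0, 1], 1.0)
        assert plan.d_bar == pytest.approx(20.0 / 3.0)
        assert plan.selected_pair == (0, 1)
        assert len(plan.candidate_pairs) == 1

    def test_coincident_centroids_selected(self):
        z, truth = blob_embedding(
            [[0, 0], [0, 0], [60, 0], [0, 60], [60, 60]], [20, 20, 20, 20, 20],
            spread=0.5, seed=3,
        )
        plan = build_merge_plan(z, state_from(z, truth))
        assert plan.selected_pair == (0, 1)

    def test_equal_intra_gives_unit_weights_and_plain_mean(self):
        # symmetric configuration with identical point layout per cluster
        offsets = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        template = np.array([[-0.5, 0.0], [0.5, 0.0]])
        pts = np.vstack([o + template for o in offsets])
        labels = np.repeat(np.arange(4), 2)
        plan = build_merge_plan(pts.T, state_from(pts.T, labels))
        offdiag = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(plan.w[offdiag], 1.0, atol=1e-12)
        iu, ju = np.triu_indices(4, 1)
        np.testing.assert_allclose(plan.d_bar, plan.d_inter[iu, ju].mean(), atol=1e-12)

    def test_k1_errors(self):
        z = np.zeros((2, 5))
        state = ClusterState(np.zeros(5, dtype=int), np.zeros((2, 1)), 1)
        with pytest.raises(ValueError):
            build_merge_plan(z, state)


class TestApplyMerge:
    def test_singleton_midpoint(self):
        z = np.array([[0.0, 2.0]])
        state = state_from(z, np.array([0, 1]))
        merged = apply_merge(z, state, (0, 1))
        assert merged.K == 1
        assert merged.centroids[0, 0] == pytest.approx(1.0)

    def test_cell_count_conserved_and_centroid_definition(self):
        rng = np.random.default_rng(5)
        z, labels = random_instance(rng, k_max=5)
        state = state_from(z, labels)
        merged = apply_merge(z, state, (0, 1))
        assert merged.labels.size == labels.size
        assert merged.K == state.K - 1
        np.testing.assert_allclose(merged.centroids, compute_centroids(z, merged.labels))

    def test_invalid_pair(self):
        z = np.zeros((1, 4))
        state = state_from(z, np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            apply_merge(z, state, (0, 0))
        with pytest.raises(ValueError):
            apply_merge(z, state, (0, 5))


class TestMergeUntilStable:
    def test_fixed_point_when_no_candidates(self):
        z, truth = blob_embedding([[0, 0], [50, 0], [0, 50]], [30, 30, 30], seed=6)
        state = state_from(z, truth)
        out, n_merges = merge_until_stable(z, state)
        assert n_merges == 0
        assert ari(out.labels, truth) == 1.0

    def test_overclustered_blobs_collapse(self):
        # 12 micro-clusters over 4 well-separated blobs -> K = 4, pure
        z, truth = blob_embedding(
            [[0, 0], [40, 0], [0, 40], [40, 40]], [45, 45, 45, 45],
            spread=1.0, seed=7,
        )
        rng = np.random.default_rng(8)
        micro = truth * 3 + rng.integers(0, 3, truth.size)
        state = state_from(z, micro)
        assert state.K == 12
        out, n_merges = merge_until_stable(z, state)
        assert out.K == 4
        assert ari(out.labels, truth) == 1.0
        assert n_merges == 8

    def test_k_monotone_and_bounded_merges(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            z, labels = random_instance(rng, k_max=8)
            state = state_from(z, labels)
            out, n_merges = merge_until_stable(z, state)
            assert out.K <= state.K
            assert out.K >= 2 or state.K == 1
            assert n_merges <= state.K - 2


class TestNetworkUpdate:
    def test_tol_one_runs_single_repeat(self, small_pretrained):
        from scace.cluster_init import leiden_init

        data = small_pretrained
        state = leiden_init(data["emb"], resolution=2.0, n_neighbors=10, seed=0)
        _, _, _, hist = network_update(
            data["model"].copy(), data["counts"], data["x_norm"], state,
            tol_fraction=1.0, seed=0,
        )
        assert len(hist) == 1

    def test_ari_not_degraded_with_true_k_init(self, small_pretrained):
        data = small_pretrained
        truth = data["labels"]
        state = state_from(data["emb"].z, truth)
        ari_before = 1.0
        _, emb2, state2, _ = network_update(
            data["model"].copy(), data["counts"], data["x_norm"], state, seed=0,
        )
        assert ari(truth, state2.labels) >= ari_before - 1e-12

    def test_lambda_zero_still_updates_labels(self, small_pretrained):
        data = small_pretrained
        state = state_from(data["emb"].z, data["labels"])
        _, _, state2, hist = network_update(
            data["model"].copy(), data["counts"], data["x_norm"], state,
            lambda_=0.0, max_repeats=2, seed=0,
        )
        assert state2.K >= 1
        assert all(np.isfinite(h["loss"]) for h in hist)
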