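import numpy as np
import pytest

from synergait import (MuscleSynergyFeatures, SimConfig, minmax_normalize, ms_features,
                       nnmf, normalize_weights, simulate_recording)


def rank1_svd_residual(E):
    """Independent oracle: the best rank-1 Frobenius approximation error is
    sqrt(sum of squared singular values beyond the first) (Eckart-Young);
    for a nonnegative matrix the leading singular pair is nonnegative
    (Perron-Frobenius), so this equals the best k=1 NNMF residual."""
    s = np.linalg.svd(E, compute_uv=False)
    return float(np.sqrt(np.sum(s[1:] ** 2)))


class TestMinmaxNormalize:
    def test_affine_map_per_channel(self):
        out = minmax_normalize(np.array([[2.0, 4.0, 6.0]]))
        assert np.allclose(out, [[0.0, 0.5, 1.0]])

    def test_constant_channel_maps_to_zero(self):
        out = minmax_normalize(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert np.allclose(out[0], 0.0)
        assert np.allclose(out[1], [0.0, 0.5, 1.0])

    def test_output_range_per_nonconstant_channel(self, rng):
        x = rng.standard_normal((4, 100))
        out = minmax_normalize(x)
        assert np.allclose(out.min(axis=1), 0.0)
        assert np.allclose(out.max(axis=1), 1.0)

    def test_joint_normalization_preserves_channel_ratios(self):
        x = np.array([[0.0, 10.0], [0.0, 5.0]])
        out = minmax_normalize(x, per_channel=False)
        assert np.allclose(out, [[0.0, 1.0], [0.0, 0.5]])


class TestNnmf:
    def test_exact_rank_one_recovery(self, rng):
        w = np.array([0.2, 1.0, 0.6, 0.1])
        h = rng.random(400)
        model = normalize_weights(nnmf(np.outer(w, h), k=1, seed=0))
        assert np.allclose(model.W[:, 0], w, atol=1e-3)

    def test_matches_svd_oracle_at_k1(self, rng):
        for _ in range(10):
            E = rng.random((4, 400))
            model = nnmf(E, k=1, n_restarts=5, seed=1)
            oracle = rank1_svd_residual(E)
            assert model.residual <= oracle * (1 + 1e-6) + 1e-12

    def test_zero_matrix(self):
        model = nnmf(np.zeros((4, 50)), k=1, seed=0)
        assert model.residual == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(model.W @ model.H, 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nnmf(np.array([[1.0, -1.0]]), k=1)
        with pytest.raises(ValueError, match="k"):
            nnmf(np.ones((2, 5)), k=0)
        with pytest.raises(ValueError, match="k"):
            nnmf(np.ones((2, 5)), k=3)

    def test_residual_monotone_within_restart(self, rng):
        # residual after n+1 multiplicative updates never exceeds residual
        # after n, for the same initialization (tol=0 disables early stop)
        E = rng.random((4, 60))
        prev = np.inf
        for it in range(1, 30, 3):
            m = nnmf(E, k=2, n_restarts=1, max_iter=it, tol=0.0, seed=3)
            assert m.residual <= prev + 1e-12
            prev = m.residual

    def test_restart_dominance(self, rng):
        # the 20-restart best can never be worse than the single-restart
        # result with the same seed (restart 0 is shared)
        for seed in range(5):
            E = rng.random((4, 80))
            r20 = nnmf(E, k=2, n_restarts=20, seed=seed).residual
            r1 = nnmf(E, k=2, n_restarts=1, seed=seed).residual
            assert r20 <= r1 + 1e-12

    def test_residual_field_consistent(self, rng):
        E = rng.random((4, 100))
        m = nnmf(E, k=1, seed=0)
        assert m.residual == pytest.approx(np.linalg.norm(E - m.W @ m.H), rel=1e-9)


class TestNormalizeWeights:
    def test_already_normalized_column_unchanged(self):
        from synergait.synergy import SynergyModel

        W = np.array([[0.2], [1.0], [0.6], [0.1]])
        H = np.ones((1, 5))
        m = normalize_weights(SynergyModel(W, H, 0.0, 1, 0))
        assert np.allclose(m.W, W)

    def test_division_by_column_max(self):
        from synergait.synergy import SynergyModel

        W = np.array([[1.0], [2.0], [4.0], [2.0]])
        H = np.ones((1, 5))
        m = normalize_weights(SynergyModel(W, H, 0.0, 1, 0))
        assert np.allclose(m.W[:, 0], [0.25, 0.5, 1.0, 0.5])

    def test_product_invariant(self, rng):
        from synergait.synergy import SynergyModel

        W = rng.random((4, 2)) + 0.1
        H = rng.random((2, 30))
        m = SynergyModel(W, H, 0.0, 1, 0)
        n = normalize_weights(m)
        assert np.allclose(m.W @ m.H, n.W @ n.H, atol=1e-12)
        assert np.allclose(n.W.max(axis=0), 1.0)

    def test_zero_column_left_with_warning(self):
        from synergait.synergy import SynergyModel

        W = np.array([[0.0, 1.0], [0.0, 0.5]])
        H = np.ones((2, 4))
        with pytest.warns(UserWarning, match="all-zero"):
            n = normalize_weights(SynergyModel(W, H, 0.0, 1, 0))
        assert np.allclose(n.W[:, 0], 0.0)


class TestSynergyRecovery:
    @pytest.mark.parametrize("K", [1, 2])
    def test_recovers_true_weights_from_noiseless_envelope(self, K):
        if K == 1:
            W = np.array([[1.0], [0.3], [0.25], [0.7]])
            centers, widths = ((0.05, 0.45),), ((0.06, 0.1),)
        else:
            W = np.array([[1.0, 0.05], [0.05, 1.0], [0.1, 0.85], [0.8, 0.1]])
            centers, widths = ((0.05,), (0.42,)), ((0.06,), (0.1,))
        cfg = SimConfig(duration_s=5.0, seed=9, true_weights=W,
                        burst_centers=centers, burst_widths=widths,
                        burst_shape="gauss", emg_noise_floor=0.0)
        rec = simulate_recording(cfg)
        model = normalize_weights(nnmf(rec.truth_envelope, k=K, n_restarts=20, seed=4))
        # relative reconstruction error is tiny: the envelope has
        # nonnegative rank K by construction
        rel = model.residual / np.linalg.norm(rec.truth_envelope)
        assert rel < 1e-3
        # match recovered columns to truth by best cosine
        for j in range(K):
            cos = [
                np.dot(model.W[:, i], W[:, j])
                / (np.linalg.norm(model.W[:, i]) * np.linalg.norm(W[:, j]))
                for i in range(K)
            ]
            assert max(cos) >= 0.95


class TestMsFeatures:
    @pytest.mark.parametrize("k,dim", [(1, 4), (2, 8), (3, 12)])
    def test_dimensionality(self, rng, k, dim):
        X = rng.random((3, 4, 40))
        assert ms_features(X, k=k, n_restarts=3, seed=0).shape == (3, dim)

    def test_rank_one_window_yields_its_weights(self, rng):
        w = np.array([0.2, 1.0, 0.6, 0.1])
        h = rng.random(200)
        feat = ms_features(np.outer(w, h)[np.newaxis], k=1, n_restarts=5, seed=0)[0]
        assert np.allclose(feat, w, atol=2e-3)

    def test_zero_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            feat = ms_features(np.zeros((1, 4, 50)), k=1, n_restarts=2, seed=0)
        assert np.allclose(feat, 0.0)

    def test_batch_matches_per_window_factorization(self, rng):
        # the vectorized extractor must equal calling nnmf window by window
        # with the seed derived from (master seed, window index)
        X = rng.random((3, 4, 60)) + 0.05
        batch = ms_features(X, k=1, n_restarts=4, seed=7)
        for i in range(3):
            E = minmax_normalize(X[i], per_channel=False)
            m = normalize_weights(nnmf(E, k=1, n_restarts=4, seed=[7, i]))
            assert np.allclose(batch[i], m.W[:, 0], atol=1e-10)

    def test_feature_independent_of_batch_composition(self, rng):
        X = rng.random((5, 4, 50))
        full = ms_features(X, k=1, n_restarts=3, seed=2)
        sub = ms_features(X[:2], k=1, n_restarts=3, seed=2)
        assert np.allclose(full[:2], sub)

    def test_sklearn_param_contract(self):
        est = MuscleSynergyFeatures(k=2, n_restarts=7)
        assert MuscleSynergyFeatures(**est.get_params()).get_params() == est.get_params()
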