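import warnings

import numpy as np
import pytest
from scipy.integrate import quad

import spica
from spica.constrained_ica import _GAUSS_BASELINE


def _laplace_mixture(seed, k=2, n=5000):
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(k, n))
    M = rng.standard_normal((k, k))
    return M @ S, M, S


class TestWhiten:
    def test_unit_covariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 3)) @ rng.standard_normal((3, 4000))
        X -= X.mean(axis=1, keepdims=True)
        Z, T, T_inv = spica.whiten(X, n_components=3)
        np.testing.assert_allclose(Z @ Z.T / Z.shape[1], np.eye(3),
                                   atol=1e-8)
        np.testing.assert_allclose(T @ T_inv, np.eye(3), atol=1e-10)

    def test_inverse_matches_pinv_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 500))
        X -= X.mean(axis=1, keepdims=True)
        Z, T, T_inv = spica.whiten(X)
        np.testing.assert_allclose(T_inv, np.linalg.pinv(T), atol=1e-8)

    def test_whitened_input_nearly_orthogonal_transform(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 200000))
        X -= X.mean(axis=1, keepdims=True)
        Z, T, _ = spica.whiten(X)
        # already-white data: T is close to orthogonal
        np.testing.assert_allclose(T @ T.T, np.eye(3), atol=0.05)

    def test_rank_deficiency_reported(self):
        X = np.ones((3, 1)) @ np.random.default_rng(3).random((1, 50))
        X -= X.mean(axis=1, keepdims=True)
        with pytest.raises(ValueError, match="rank"):
            spica.whiten(X, n_components=3)


class TestNegentropyContrast:
    def test_gaussian_baseline_quadrature(self):
        # independent oracle: quadrature of log cosh against the normal pdf
        oracle, _ = quad(lambda x: np.log(np.cosh(x)) *
                         np.exp(-x**2 / 2) / np.sqrt(2 * np.pi), -10, 10,
                         epsabs=1e-12, epsrel=1e-12)
        assert oracle == pytest.approx(0.3746, abs=5e-5)
        assert _GAUSS_BASELINE == pytest.approx(oracle, abs=1e-9)
        assert spica.gauss_logcosh_baseline() == pytest.approx(oracle,
                                                               abs=1e-9)

    def test_gaussian_limit_vanishes(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((2, 100000))
        for w in ([1, 0], [0.6, 0.8]):
            assert spica.negentropy_contrast(np.array(w), Z) <= 1e-3

    def test_bernoulli_source_positive(self):
        rng = np.random.default_rng(5)
        Z = rng.choice([-1.0, 1.0], size=(1, 50000))
        J = spica.negentropy_contrast(np.array([1.0]), Z)
        # closed form: E[log cosh(+-1)] = log cosh 1, so
        # J = (log cosh 1 - E[log cosh v])^2 exactly
        closed = (np.log(np.cosh(1.0)) - _GAUSS_BASELINE) ** 2
        assert J == pytest.approx(closed, rel=1e-6)
        assert J > 1e-3

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spica.negentropy_contrast(np.zeros(2), np.ones((2, 10)))


class TestFit:
    def test_uniform_sources_amari_recovery(self):
        # sub-Gaussian sources; median Amari index over 10 seeds
        scores = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            k = int(rng.integers(2, 6))
            n = int(rng.integers(2000, 5001))
            S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(k, n))
            M = rng.standard_normal((k, k))
            dec = spica.fit(M @ S, spica.ICAConfig(n_components=k, seed=seed))
            scores.append(spica.amari_index(dec.W @ M))
        assert np.median(scores) < 0.05

    def test_exact_factorization_full_rank(self):
        X, M, S = _laplace_mixture(6, k=3, n=4000)
        dec = spica.fit(X, spica.ICAConfig(n_components=3, seed=0))
        X_hat = dec.A @ dec.C_S + dec.cx_mean[:, None]
        # sample-wise correlation of reconstruction vs input
        for i in range(3):
            r = np.corrcoef(X[i], X_hat[i])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_unit_variance_constraint(self):
        X, _, _ = _laplace_mixture(7, k=4, n=3000)
        dec = spica.fit(X, spica.ICAConfig(n_components=4, seed=1))
        assert np.all(np.abs(np.var(dec.C_S, axis=1) - 1) <= 1e-3)
        # pairwise decorrelation
        C = np.corrcoef(dec.C_S)
        np.testing.assert_allclose(C - np.diag(np.diag(C)),
                                   np.zeros_like(C), atol=1e-3)

    def test_seed_invariance_up_to_permutation(self):
        X, M, _ = _laplace_mixture(8, k=3, n=6000)
        d1 = spica.fit(X, spica.ICAConfig(n_components=3, seed=10))
        d2 = spica.fit(X, spica.ICAConfig(n_components=3, seed=77))
        # W1 = P D W2 ==> W1 @ pinv(W2) is a scaled permutation
        assert spica.amari_index(d1.W @ np.linalg.pinv(d2.W)) < 0.05

    def test_objective_monotone_on_fixture(self):
        X, _, _ = _laplace_mixture(9, k=2, n=5000)
        dec = spica.fit(X, spica.ICAConfig(n_components=2, seed=2))
        h = np.asarray(dec.objective_history)
        assert np.all(np.diff(h) >= -1e-6)

    def test_gaussian_input_diagnostics(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((3, 100000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dec = spica.fit(X, spica.ICAConfig(n_components=3, seed=0,
                                               max_iter=100))
        assert np.all(dec.negentropy <= 1e-2)

    def test_penalty_free_limit_same_subspace(self):
        # with penalties disabled the update is the classical negentropy
        # fixed point; both must span the same unmixing subspace
        X, _, _ = _laplace_mixture(11, k=2, n=5000)
        d_al = spica.fit(X, spica.ICAConfig(n_components=2, seed=3))
        d_fp = spica.fit(X, spica.ICAConfig(n_components=2, seed=3,
                                            use_penalty=False))
        # principal angles between row spaces of the two unmixing matrices
        q1, _ = np.linalg.qr(d_al.W.T)
        q2, _ = np.linalg.qr(d_fp.W.T)
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-3

    def test_fastica_cross_check(self):
        # independent implementation recovering the same mixing (up to P, D)
        sklearn = pytest.importorskip("sklearn.decomposition")
        X, M, _ = _laplace_mixture(12, k=3, n=6000)
        dec = spica.fit(X, spica.ICAConfig(n_components=3, seed=4))
        ica = sklearn.FastICA(n_components=3, whiten="unit-variance",
                              random_state=0, max_iter=1000)
        ica.fit(X.T)
        W_ref = ica.components_
        assert spica.amari_index(dec.W @ np.linalg.pinv(W_ref)) < 0.05

    def test_bad_component_count(self):
        X, _, _ = _laplace_mixture(13, k=2, n=500)
        with pytest.raises(ValueError, match="n_components"):
            spica.fit(X, spica.ICAConfig(n_components=5))

    def test_nonconvergence_warns_not_raises(self):
        X, _, _ = _laplace_mixture(14, k=3, n=2000)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            dec = spica.fit(X, spica.ICAConfig(n_components=3, seed=0,
                                               max_iter=1))
        assert not np.all(dec.converged)


class TestReconstruct:
    def test_lossless_pipeline(self, noiseless_synth):
        ms, truth = noiseless_synth
        X, bounds = spica.concatenate(ms)
        pca = spica.pca_reduce(X.T, threshold=1.0)
        sa = spica.sparse_approximate(pca.reduced, kind="identity")
        dec = spica.fit(sa.coeffs, spica.ICAConfig(seed=0),
                        dictionary=sa.dictionary, block_slices=bounds)
        recons = spica.reconstruct(dec, ms, pca, dictionary=sa.dictionary)
        for blk, X_hat in zip(ms.blocks, recons):
            r, mean, _ = spica.sample_correlations(blk.values, X_hat)
            np.testing.assert_allclose(r, 1.0, atol=1e-6)

    def test_zero_basis_gives_mean_matrix(self, noiseless_synth):
        ms, _ = noiseless_synth
        X, bounds = spica.concatenate(ms)
        pca = spica.pca_reduce(X.T, threshold=1.0)
        sa = spica.sparse_approximate(pca.reduced, kind="identity")
        dec = spica.fit(sa.coeffs, spica.ICAConfig(seed=0),
                        dictionary=sa.dictionary, block_slices=bounds)
        dec.A = np.zeros_like(dec.A)
        dec.cx_mean = np.zeros_like(dec.cx_mean)
        recons = spica.reconstruct(dec, ms, pca, dictionary=sa.dictionary)
        for blk, X_hat in zip(ms.blocks, recons):
            expect = np.tile(blk.values.mean(axis=1, keepdims=True),
                             (1, blk.n_samples))
            np.testing.assert_allclose(X_hat, expect, atol=1e-8)
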