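"""GP core: kernel, marginal likelihood, fitting, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import cho_solve, cholesky

from fluxgpr import gpr
from fluxgpr.io_formats.model_io import model_record

from conftest import random_gp_instance


class TestKernel:
    def test_self_evaluation_is_signal_variance(self):
        hyp = gpr.Hyperparameters(2.5, np.array([1.0, 3.0]), 0.0)
        K = gpr.kernel_matrix([[0.3, -1.2]], [[0.3, -1.2]], hyp)
        assert K[0, 0] == pytest.approx(2.5)

    def test_hand_evaluated_unit_case(self):
        # D=2, unit lengthscales, points (0,0) and (1,1): exp(-1)
        hyp = gpr.Hyperparameters(1.0, np.ones(2), 0.0)
        K = gpr.kernel_matrix([[0.0, 0.0]], [[1.0, 1.0]], hyp)
        assert K[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_huge_lengthscale_removes_coordinate(self):
        base = gpr.Hyperparameters(1.0, np.array([1.0, 1e12]), 0.0)
        a = gpr.kernel_matrix([[0.0, 0.0]], [[0.5, 0.0]], base)
        b = gpr.kernel_matrix([[0.0, 0.0]], [[0.5, 1000.0]], base)
        assert a[0, 0] == pytest.approx(b[0, 0], rel=1e-9)

    def test_dimension_mismatch_names_both(self):
        hyp = gpr.Hyperparameters(1.0, np.ones(3), 0.0)
        with pytest.raises(ValueError, match="D=2.*D=3|D=3.*D=2"):
            gpr.kernel_matrix(np.zeros((2, 2)), np.zeros((2, 2)), hyp)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric_and_psd_on_self(self, seed):
        rng = np.random.default_rng(seed)
        n, D = int(rng.integers(2, 15)), int(rng.integers(1, 5))
        X = rng.standard_normal((n, D))
        hyp = gpr.Hyperparameters(
            float(rng.uniform(0.1, 5)), rng.uniform(0.2, 4, D), 0.0
        )
        K = gpr.kernel_matrix(X, X, hyp)
        assert np.max(np.abs(K - K.T)) == 0.0
        w = np.linalg.eigvalsh(K)
        assert w.min() >= -1e-8 * np.trace(K) / n


class TestLogMarginalLikelihood:
    def test_scalar_closed_form(self):
        # n=1: lml = -y^2/(2c) - log(c)/2 - log(2 pi)/2 with c = k + noise
        hyp = gpr.Hyperparameters(1.5, np.array([1.0]), 0.5)
        tm = gpr.TrainingMatrix(
            np.array([[0.0], [100.0]]), np.array([0.7, 0.0]),
            np.zeros(1), np.ones(1), 0.0, 1.0,
        )
        # the two points are ~independent; check against the 2x2 closed form
        c = 1.5 + 0.5
        lml, _ = gpr.log_marginal_likelihood(hyp, tm)
        expected = (-0.7**2 / (2 * c) - 0.5 * np.log(c) - 0.5 * np.log(2 * np.pi)) \
            + (-0.0 - 0.5 * np.log(c) - 0.5 * np.log(2 * np.pi))
        assert lml == pytest.approx(expected, rel=1e-9)

    def test_quadratic_term_scale_equivariance(self):
        # scaling y by 2 and both variances by 4 leaves y^T Kn^-1 y unchanged
        rng = np.random.default_rng(5)
        tm, hyp = random_gp_instance(rng, 10, 2)
        hyp4 = gpr.Hyperparameters(4 * hyp.signal_var, hyp.lengthscales,
                                   4 * hyp.noise_var)
        tm2 = gpr.TrainingMatrix(tm.X, 2 * tm.y, tm.x_mean, tm.x_scale, 0.0, 1.0)

        def quad(h, t):
            K = gpr.kernel_matrix(t.X, t.X, h) + h.noise_var * np.eye(t.n)
            L = cholesky(K, lower=True)
            return float(t.y @ cho_solve((L, True), t.y))

        assert quad(hyp, tm) == pytest.approx(quad(hyp4, tm2), rel=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, D = int(rng.integers(4, 12)), int(rng.integers(1, 4))
        tm, hyp = random_gp_instance(rng, n, D)
        _, grad = gpr.log_marginal_likelihood(hyp, tm)
        theta = np.concatenate((
            [np.log(hyp.signal_var)], np.log(hyp.lengthscales),
            [np.log(hyp.noise_var)],
        ))
        eps = 1e-6
        for i in range(theta.size):
            tp, tmn = theta.copy(), theta.copy()
            tp[i] += eps
            tmn[i] -= eps

            def unpack(t):
                return gpr.Hyperparameters(np.exp(t[0]), np.exp(t[1:1 + D]),
                                           np.exp(t[1 + D]))

            fp, _ = gpr.log_marginal_likelihood(unpack(tp), tm)
            fm, _ = gpr.log_marginal_likelihood(unpack(tmn), tm)
            fd = (fp - fm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestPredict:
    def test_noise_free_interpolation(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        tm = gpr.TrainingMatrix(X, y, np.zeros(2), np.ones(2), 0.0, 1.0)
        hyp = gpr.Hyperparameters(1.0, np.array([1.5, 1.5]), 0.0)
        model = _manual_model(tm, hyp)
        p = gpr.predict(model, X)
        np.testing.assert_allclose(p.mean, y, atol=1e-7)
        np.testing.assert_allclose(p.sigma, 0.0, atol=1e-4)

    def test_prior_reversion_far_from_data(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8) + 3.0
        tm = gpr.TrainingMatrix.from_raw(X, y)
        hyp = gpr.Hyperparameters(1.0, np.array([0.5, 0.5]), 0.01)
        model = _manual_model(tm, hyp)
        p = gpr.predict(model, np.array([[50.0, 50.0]]))
        assert p.mean[0] == pytest.approx(tm.y_mean, abs=1e-6)
        assert p.sigma[0] == pytest.approx(np.sqrt(1.0) * tm.y_scale, rel=1e-6)

    def test_single_training_point_hand_solution(self):
        # k(x*,x1)=0.5, sigma_s^2=1, sigma_n^2=0.25:
        # mean = 0.5 y1 / 1.25 = 0.4 y1; var = 1 - 0.25/1.25 = 0.8
        ell = 1.0
        dist = np.sqrt(-2.0 * np.log(0.5))  # distance giving k = 0.5
        X = np.array([[0.0], [100.0]])  # second point is inert padding
        y1 = 0.9
        hyp = gpr.Hyperparameters(1.0, np.array([ell]), 0.25)
        tm = gpr.TrainingMatrix(X, np.array([y1, 0.0]), np.zeros(1),
                                np.ones(1), 0.0, 1.0)
        model = _manual_model(tm, hyp)
        p = gpr.predict(model, np.array([[dist]]))
        assert p.mean[0] == pytest.approx(0.4 * y1, rel=1e-6)
        assert p.sigma[0] == pytest.approx(np.sqrt(0.8), rel=1e-6)

    def test_sigma_never_exceeds_prior(self):
        rng = np.random.default_rng(4)
        tm, hyp = random_gp_instance(rng, 15, 3)
        model = _manual_model(tm, hyp)
        q = rng.uniform(-5, 5, size=(200, 3))
        p = gpr.predict(model, q)
        prior = np.sqrt(hyp.signal_var) * tm.y_scale
        assert np.all(p.sigma <= prior + 1e-10)

    def test_chunking_is_bitwise_invariant(self):
        rng = np.random.default_rng(6)
        tm, hyp = random_gp_instance(rng, 40, 3)
        model = _manual_model(tm, hyp)
        q = rng.uniform(-3, 3, size=(97, 3))
        full = gpr.predict(model, q)
        for cs in (1, 7, 64, 4096):
            part = gpr.predict(model, q, chunk_size=cs)
            assert np.array_equal(full.mean, part.mean)
            assert np.array_equal(full.sigma, part.sigma)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_brute_force_oracle_equivalence(self, seed):
        """Cholesky path vs explicit dense inverse on small instances."""
        rng = np.random.default_rng(seed)
        n, D = int(rng.integers(3, 20)), int(rng.integers(1, 5))
        tm, hyp = random_gp_instance(rng, n, D)
        model = _manual_model(tm, hyp)
        q = rng.uniform(-3, 3, size=(10, D))
        p = gpr.predict(model, q)

        Kn = gpr.kernel_matrix(tm.X, tm.X, hyp) + \
            (hyp.noise_var + model.jitter) * np.eye(n)
        Kinv = np.linalg.inv(Kn)
        Ks = gpr.kernel_matrix(q, tm.X, hyp)
        mean_bf = Ks @ Kinv @ tm.y
        var_bf = hyp.signal_var - np.einsum("qi,ij,qj->q", Ks, Kinv, Ks)
        scale = max(1.0, np.max(np.abs(mean_bf)))
        np.testing.assert_allclose(p.mean, mean_bf, rtol=1e-8,
                                   atol=1e-8 * scale)
        np.testing.assert_allclose(p.sigma**2, np.maximum(var_bf, 0),
                                   rtol=1e-7, atol=1e-8)

    def test_variance_shrinks_when_training_point_added(self):
        rng = np.random.default_rng(8)
        for seed in range(10):
            r = np.random.default_rng(seed)
            tm, hyp = random_gp_instance(r, 10, 2)
            model10 = _manual_model(tm, hyp)
            extra_x = r.uniform(-2, 2, size=(1, 2))
            X11 = np.vstack([tm.X, extra_x])
            y11 = np.append(tm.y, 0.0)
            tm11 = gpr.TrainingMatrix(X11, y11, tm.x_mean, tm.x_scale, 0.0, 1.0)
            model11 = _manual_model(tm11, hyp)
            q = r.uniform(-2, 2, size=(20, 2))
            s10 = gpr.predict(model10, q).sigma
            s11 = gpr.predict(model11, q).sigma
            assert np.all(s11 <= s10 + 1e-8)


class TestFit:
    def test_recovers_planted_lengthscales(self):
        true_ell = np.array([0.5, 2.0, 50.0])
        rng = np.random.default_rng(100)
        X = rng.uniform(-2, 2, size=(300, 3))
        hyp = gpr.Hyperparameters(1.0, true_ell, 1e-8)
        K = gpr.kernel_matrix(X, X, hyp) + 0.01 * np.eye(300)
        y = np.linalg.cholesky(K) @ rng.standard_normal(300)
        tm = gpr.TrainingMatrix(X, y, np.zeros(3), np.ones(3), 0.0, 1.0)
        m = gpr.fit(tm, gpr.FitConfig(restarts=3, seed=0, maxiter=150))
        ell = m.hyperparameters.lengthscales
        for i in (0, 1):  # informative dimensions
            assert 1 / 1.5 <= ell[i] / true_ell[i] <= 1.5
        # the planted-irrelevant dimension ends up much longer than the
        # data spread along it
        assert ell[2] > 5 * X[:, 2].std()

    def test_constant_target_degenerates_gracefully(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        tm = gpr.TrainingMatrix.from_raw(X, np.full(20, 3.7))
        m = gpr.fit(tm, gpr.FitConfig(restarts=2, seed=1, maxiter=60))
        p = gpr.predict(m, X)
        np.testing.assert_allclose(p.mean, 3.7, atol=1e-3)

    def test_duplicate_rows_survive_via_jitter(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        y = np.array([1.0] * 5 + [2.0] * 5)
        tm = gpr.TrainingMatrix.from_raw(X, y)
        m = gpr.fit(tm, gpr.FitConfig(restarts=2, seed=0, maxiter=60))
        assert np.isfinite(m.log_marginal_likelihood)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(9)
        tm, _ = random_gp_instance(rng, 30, 2)
        cfg = gpr.FitConfig(restarts=3, seed=77, maxiter=60)
        m1, m2 = gpr.fit(tm, cfg), gpr.fit(tm, cfg)
        np.testing.assert_array_equal(m1.hyperparameters.lengthscales,
                                      m2.hyperparameters.lengthscales)


class TestStandalonePredict:
    def test_parity_with_native_predict(self, fitted_gpp_model, schema):
        rng = np.random.default_rng(10)
        model = fitted_gpp_model
        q = model.training.X[:20] * model.training.x_scale + model.training.x_mean
        q = q + rng.normal(0, 0.01, q.shape)
        rec = model_record(model, schema)
        native = gpr.predict(model, q)
        portable = gpr.standalone_predict(rec, q)
        np.testing.assert_allclose(portable.mean, native.mean, rtol=0,
                                   atol=1e-10 * max(1, np.abs(native.mean).max()))
        np.testing.assert_allclose(portable.sigma, native.sigma, rtol=0,
                                   atol=1e-10)

    def test_perturbed_lengthscale_changes_predictions(self, fitted_gpp_model,
                                                       schema):
        model = fitted_gpp_model
        q = model.training.x_mean[None, :] * 1.05
        rec = model_record(model, schema)
        base = gpr.standalone_predict(rec, q)
        rec2 = model_record(model, schema)
        rec2["theta"]["lengthscales"] = list(rec2["theta"]["lengthscales"])
        rec2["theta"]["lengthscales"][0] *= 1.001
        pert = gpr.standalone_predict(rec2, q)
        assert not np.allclose(base.mean, pert.mean, rtol=0, atol=0)

    def test_sklearn_reference_parity_fixed_hyperparameters(self):
        """Independent reference GP at the same (fixed) hyperparameters."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(11)
        n, D = 40, 3
        X = rng.uniform(-2, 2, size=(n, D))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2
        ell = np.array([0.8, 1.4, 2.2])
        sv, nv = 1.7, 0.05

        kernel = ConstantKernel(sv, "fixed") * RBF(ell, "fixed")
        ref = GaussianProcessRegressor(kernel=kernel, alpha=nv,
                                       optimizer=None, normalize_y=False)
        ref.fit(X, y)
        q = rng.uniform(-2, 2, size=(25, D))
        mean_ref, std_ref = ref.predict(q, return_std=True)

        hyp = gpr.Hyperparameters(sv, ell, nv)
        tm = gpr.TrainingMatrix(X, y, np.zeros(D), np.ones(D), 0.0, 1.0)
        model = _manual_model(tm, hyp)
        ours = gpr.predict(model, q)
        np.testing.assert_allclose(ours.mean, mean_ref, atol=1e-8)
        np.testing.assert_allclose(ours.sigma, std_ref, atol=1e-6)


def _manual_model(tm: gpr.TrainingMatrix, hyp: gpr.Hyperparameters):
    """Build a TrainedGPR at fixed hyperparameters (no optimization)."""
    K = gpr.kernel_matrix(tm.X, tm.X, hyp)
    Kn = K + hyp.noise_var * np.eye(tm.n)
    L, jitter = gpr._chol_with_jitter(Kn)
    alpha = cho_solve((L, True), tm.y)
    lml = (-0.5 * float(tm.y @ alpha) - float(np.sum(np.log(np.diag(L))))
           - 0.5 * tm.n * np.log(2 * np.pi))
    return gpr.TrainedGPR(hyp, tm, alpha, L, jitter, lml)
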