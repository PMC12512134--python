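"""Per-feature GPR: likelihood, optimization, masked prediction protocol."""

import numpy as np
import pytest
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, DotProduct

from freda.exceptions import NumericalError, ProtocolError
from freda.gpr import (
    GPRHyperparams,
    aggregate_hyperparams,
    assemble_kernel_matrices,
    centralized_gpr_oracle,
    neg_log_marginal_likelihood,
    optimize_local_hyperparams,
    predicted_mean_protocol,
    predicted_variance,
)
from freda.masking import RowMask, make_row_mask

from conftest import make_latent_data

LOG2PI = np.log(2 * np.pi)


def sklearn_gp(X, y, hyper):
    kernel = ConstantKernel(hyper.sigma_k2, "fixed") * DotProduct(
        sigma_0=0.0, sigma_0_bounds="fixed"
    )
    gp = GaussianProcessRegressor(kernel=kernel, alpha=hyper.sigma_eps2, optimizer=None)
    gp.fit(X, y)
    return gp


class TestMarginalLikelihood:
    def test_scalar_closed_form(self):
        # n=1, X=[[0]], sigma_eps2=1 => K=[[1]]: NLML = x^2/2 + log(2*pi)/2
        for x in (0.0, 1.3, -2.0):
            nll = neg_log_marginal_likelihood(
                np.array([[0.0]]), np.array([x]), GPRHyperparams(1.0, 1.0)
            )
            assert nll == pytest.approx(0.5 * x**2 + 0.5 * LOG2PI, abs=1e-12)

    def test_zero_targets_leave_only_logdet_term(self, rng):
        X = rng.standard_normal((6, 3))
        hyper = GPRHyperparams(0.7, 0.4)
        K = 0.7 * X @ X.T + 0.4 * np.eye(6)
        expected = 0.5 * np.linalg.slogdet(K)[1] + 3 * LOG2PI
        assert neg_log_marginal_likelihood(X, np.zeros(6), hyper) == pytest.approx(
            expected, rel=1e-10
        )

    def test_matches_reference_gp_library(self, rng):
        """Cross-check against scikit-learn's GP log-marginal on 10 random
        instances."""
        for _ in range(10):
            n, p = int(rng.integers(3, 30)), int(rng.integers(1, 6))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            hyper = GPRHyperparams(float(rng.uniform(0.2, 3)), float(rng.uniform(0.1, 2)))
            ours = -neg_log_marginal_likelihood(X, y, hyper)
            ref = sklearn_gp(X, y, hyper).log_marginal_likelihood_value_
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(NumericalError):
            GPRHyperparams(0.0, 1.0)
        with pytest.raises(NumericalError):
            GPRHyperparams(1.0, -1.0)


class TestHyperparamOptimization:
    def simulate_gp_feature(self, seed, n=200, p=100, sk2=2.0, se2=0.5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        cov = sk2 * X @ X.T + se2 * np.eye(n)
        y = rng.multivariate_normal(np.zeros(n), cov, method="cholesky")
        return X, y

    def test_recovers_generating_variances(self):
        errs_k, errs_e = [], []
        for seed in range(4):
            X, y = self.simulate_gp_feature(seed)
            est = optimize_local_hyperparams(X, y)
            errs_k.append(abs(est.sigma_k2 - 2.0) / 2.0)
            errs_e.append(abs(est.sigma_eps2 - 0.5) / 0.5)
        assert np.median(errs_k) < 0.25
        assert np.median(errs_e) < 0.25

    def test_never_worse_than_init(self, rng):
        X = rng.standard_normal((20, 4))
        y = X @ rng.standard_normal(4)
        init = optimize_local_hyperparams(X, y)
        again = optimize_local_hyperparams(X, y, init=init)
        assert neg_log_marginal_likelihood(X, y, again) <= neg_log_marginal_likelihood(
            X, y, init
        ) + 1e-9

    def test_bounds_respected_on_adversarial_data(self):
        X = np.full((5, 2), 1e6)
        y = np.full(5, -1e6)
        est = optimize_local_hyperparams(X, y)
        for v in (est.sigma_k2, est.sigma_eps2):
            assert 1e-6 - 1e-12 <= v <= 1e6 + 1e-6


class TestHyperparamAggregation:
    def test_mean_of_constants_and_two_point_mean(self):
        same = {f"c{i}": GPRHyperparams(0.8, 0.3) for i in range(3)}
        agg = aggregate_hyperparams(same)
        assert agg.sigma_k2 == pytest.approx(0.8, abs=1e-8)
        assert agg.sigma_eps2 == pytest.approx(0.3, abs=1e-8)
        two = {"a": GPRHyperparams(1, 1), "b": GPRHyperparams(3, 3)}
        agg = aggregate_hyperparams(two)
        assert (agg.sigma_k2, agg.sigma_eps2) == (pytest.approx(2, abs=1e-8),) * 2

    def test_matches_plain_mean_and_permutation_invariant(self, rng):
        vals = {f"c{i}": GPRHyperparams(*rng.uniform(0.1, 5, 2)) for i in range(8)}
        agg = aggregate_hyperparams(vals)
        plain_k = np.mean([v.sigma_k2 for v in vals.values()])
        plain_e = np.mean([v.sigma_eps2 for v in vals.values()])
        assert agg.sigma_k2 == pytest.approx(plain_k, abs=1e-7)
        assert agg.sigma_eps2 == pytest.approx(plain_e, abs=1e-7)
        shuffled = dict(reversed(list(vals.items())))
        agg2 = aggregate_hyperparams(shuffled)
        assert agg2.sigma_k2 == agg.sigma_k2

    def test_weighted_variant_and_empty_error(self):
        two = {"a": GPRHyperparams(1, 1), "b": GPRHyperparams(3, 3)}
        agg = aggregate_hyperparams(two, sample_sizes={"a": 1, "b": 3})
        assert agg.sigma_k2 == pytest.approx(2.5, abs=1e-7)
        with pytest.raises(ProtocolError):
            aggregate_hyperparams({})


class TestKernelAssembly:
    def test_identity_block(self):
        K, K_star, _ = assemble_kernel_matrices(
            np.eye(3), np.zeros((2, 3)), np.eye(2), GPRHyperparams(1.0, 1.0), 3
        )
        np.testing.assert_allclose(K, 2 * np.eye(3))
        np.testing.assert_allclose(K_star, 0)

    def test_kernel_scales_linearly_with_prior_variance(self, rng):
        g_ts = rng.standard_normal((2, 3))
        _, K1, _ = assemble_kernel_matrices(
            np.eye(3), g_ts, np.eye(2), GPRHyperparams(0.5, 1.0), 3
        )
        _, K2, _ = assemble_kernel_matrices(
            np.eye(3), g_ts, np.eye(2), GPRHyperparams(1.0, 1.0), 3
        )
        np.testing.assert_allclose(2 * K1, K2)

    def test_asymmetric_gram_rejected(self, rng):
        bad = rng.standard_normal((4, 4))
        with pytest.raises(ProtocolError):
            assemble_kernel_matrices(
                bad, np.zeros((2, 4)), np.eye(2), GPRHyperparams(1, 1), 4
            )


class TestPredictionProtocol:
    def scalar_case(self):
        # X_train=[[1]], x_f=[2], X_test=[[1]], sk2=se2=1: K=2, K*=1
        hyper = GPRHyperparams(1.0, 1.0)
        K, K_star, K_ss = assemble_kernel_matrices(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]), hyper, 1
        )
        return K, K_star, K_ss

    def test_scalar_mean_and_variance(self):
        K, K_star, K_ss = self.scalar_case()
        mask = RowMask(C=np.eye(1), C_inv=np.eye(1))
        mean = predicted_mean_protocol(
            K_star, K, {"c0": np.array([2.0])}, mask, {"c0": slice(0, 1)}
        )
        assert mean[0] == pytest.approx(1.0, abs=1e-12)  # 1 * (1/2) * 2
        var = predicted_variance(K_ss, K_star, K)
        assert var[0] == pytest.approx(0.5, abs=1e-12)  # 1 - 1*(1/2)*1

    def test_identity_mask_equals_direct_product(self, rng):
        n_s, n_t = 12, 5
        X = rng.standard_normal((n_s, 4))
        Xt = rng.standard_normal((n_t, 4))
        x_f = rng.standard_normal(n_s)
        hyper = GPRHyperparams(1.3, 0.6)
        K, K_star, _ = assemble_kernel_matrices(X @ X.T, Xt @ X.T, Xt @ Xt.T, hyper, n_s)
        direct = K_star @ np.linalg.solve(K, x_f)
        mask = RowMask(C=np.eye(n_t), C_inv=np.eye(n_t))
        out = predicted_mean_protocol(K_star, K, {"c0": x_f}, mask, {"c0": slice(0, n_s)})
        np.testing.assert_allclose(out, direct, atol=1e-10)

    @pytest.mark.parametrize("n_clients", [2, 4])
    def test_split_clients_match_pooled_oracle(self, n_clients, rng):
        n_s, n_t, p = 40, 9, 6
        X = make_latent_data(rng, n_s, p)
        Xt = make_latent_data(rng, n_t, p)
        x_f = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n_s)
        hyper = GPRHyperparams(0.9, 0.2)
        oracle_mean, oracle_var = centralized_gpr_oracle(X, x_f, Xt, hyper)

        K, K_star, K_ss = assemble_kernel_matrices(X @ X.T, Xt @ X.T, Xt @ Xt.T, hyper, n_s)
        bounds = np.linspace(0, n_s, n_clients + 1).astype(int)
        slices = {f"c{i}": slice(bounds[i], bounds[i + 1]) for i in range(n_clients)}
        cols = {cid: x_f[sl] for cid, sl in slices.items()}
        mask = make_row_mask(n_t, seed=77)
        mean = predicted_mean_protocol(K_star, K, cols, mask, slices)
        var = predicted_variance(K_ss, K_star, K)
        assert np.max(np.abs(mean - oracle_mean)) < 1e-6
        assert np.max(np.abs(var - oracle_var)) < 1e-6

    def test_slice_mismatch_raises(self):
        K, K_star, _ = self.scalar_case()
        mask = RowMask(C=np.eye(1), C_inv=np.eye(1))
        with pytest.raises(ProtocolError):
            predicted_mean_protocol(
                K_star, K, {"c0": np.array([2.0, 3.0])}, mask, {"c0": slice(0, 1)}
            )


class TestPredictiveVariance:
    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(100):
            n_s, n_t, p = int(rng.integers(2, 30)), int(rng.integers(1, 10)), int(rng.integers(1, 8))
            X = rng.standard_normal((n_s, p))
            Xt = rng.standard_normal((n_t, p))
            hyper = GPRHyperparams(float(rng.uniform(0.1, 3)), float(rng.uniform(0.05, 1)))
            K, K_star, K_ss = assemble_kernel_matrices(
                X @ X.T, Xt @ X.T, Xt @ Xt.T, hyper, n_s
            )
            assert np.min(predicted_variance(K_ss, K_star, K)) >= 0.0

    def test_vanishes_at_training_point_in_noiseless_limit(self, rng):
        X = rng.standard_normal((10, 3))
        Xt = X[:1]
        hyper = GPRHyperparams(1.0, 1e-6)
        K, K_star, K_ss = assemble_kernel_matrices(X @ X.T, Xt @ X.T, Xt @ Xt.T, hyper, 10)
        assert predicted_variance(K_ss, K_star, K)[0] < 1e-4

    def test_monotone_in_training_data(self, rng):
        """Latent variance never grows when training data is added (fixed
        hyper-parameters, nested designs)."""
        X = rng.standard_normal((30, 5))
        Xt = rng.standard_normal((7, 5))
        hyper = GPRHyperparams(1.0, 0.3)
        prev = np.full(7, np.inf)
        for n in (5, 15, 30):
            Xn = X[:n]
            K, K_star, K_ss = assemble_kernel_matrices(
                Xn @ Xn.T, Xt @ Xn.T, Xt @ Xt.T, hyper, n
            )
            var = predicted_variance(K_ss, K_star, K)
            assert np.all(var <= prev + 1e-10)
            prev = var


class TestCentralizedOracle:
    def test_matches_reference_gp_predictions(self, rng):
        X = rng.standard_normal((25, 4))
        y = X @ rng.standard_normal(4) + 0.3 * rng.standard_normal(25)
        Xt = rng.standard_normal((6, 4))
        hyper = GPRHyperparams(1.1, 0.4)
        mean, var = centralized_gpr_oracle(X, y, Xt, hyper)
        gp = sklearn_gp(X, y, hyper)
        ref_mean, ref_std = gp.predict(Xt, return_std=True)
        np.testing.assert_allclose(mean, ref_mean, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(var), ref_std, atol=1e-6)

    def test_client_order_invariance(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        Xt = rng.standard_normal((4, 3))
        hyper = GPRHyperparams(1.0, 0.5)
        m1, v1 = centralized_gpr_oracle(X, y, Xt, hyper)
        perm = rng.permutation(20)
        m2, v2 = centralized_gpr_oracle(X[perm], y[perm], Xt, hyper)
        np.testing.assert_allclose(m1, m2, atol=1e-9)
        np.testing.assert_allclose(v1, v2, atol=1e-9)
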