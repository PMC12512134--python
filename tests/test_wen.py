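"""Weighted elastic net: objective, oracle optimality, federated training."""

import numpy as np
import pytest

from freda.exceptions import ConfigurationError, ProtocolError
from freda.wen import (
    TrainingSchedule,
    WENModel,
    centralized_wen_oracle,
    en_ls_baseline,
    fedavg_aggregate,
    kkt_residual,
    local_train,
    predict,
    train_federated_wen,
    wen_objective,
)

from conftest import make_latent_data


def make_model(beta, lam=1.0, alpha=0.8, weights=None, intercept=0.0):
    beta = np.asarray(beta, dtype=float)
    w = np.ones_like(beta) if weights is None else np.asarray(weights, dtype=float)
    return WENModel(beta=beta, intercept=intercept, lam=lam, alpha=alpha, weights=w)


def make_regression(rng, n=60, P=10, collinear=True):
    X = make_latent_data(rng, n, P, rank=3) if collinear else rng.standard_normal((n, P))
    beta = rng.standard_normal(P) / np.sqrt(P)
    y = 1.0 + X @ beta + 0.2 * rng.standard_normal(n)
    return X, y


class TestObjective:
    def test_null_model_gives_label_energy(self, rng):
        X = rng.standard_normal((7, 3))
        y = rng.standard_normal(7)
        model = make_model(np.zeros(3), lam=2.0)
        assert wen_objective(model, X, y) == pytest.approx(float(y @ y))

    def test_zero_lambda_is_pure_rss(self, rng):
        X = rng.standard_normal((7, 3))
        y = rng.standard_normal(7)
        model = make_model(rng.standard_normal(3), lam=0.0, intercept=0.5)
        resid = y - 0.5 - X @ model.beta
        assert wen_objective(model, X, y) == pytest.approx(float(resid @ resid))

    def test_hand_computed_example(self):
        # X=[[1],[2]], y=(1,2), beta=(1), w=(1), lam=1, alpha=0.8:
        # RSS=0, penalty = 0.8*1 + 0.5*0.2*1 = 0.9
        model = make_model([1.0], lam=1.0, alpha=0.8)
        X = np.array([[1.0], [2.0]])
        y = np.array([1.0, 2.0])
        assert wen_objective(model, X, y) == pytest.approx(0.9, abs=1e-12)


class TestLocalTrain:
    def test_stationary_point_is_fixed(self, rng):
        X, y = make_regression(rng, collinear=False)
        ols = centralized_wen_oracle(X, y, np.zeros(X.shape[1]), 1.0, 0.8)
        out = local_train(ols, X, y, epochs=10, lr=1e-4)
        np.testing.assert_allclose(out.beta, ols.beta, atol=1e-8)
        assert out.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_huge_lambda_shrinks_coefficients_monotonically(self, rng):
        X, y = make_regression(rng)
        model = make_model(rng.standard_normal(X.shape[1]), lam=1e6)
        norms = [np.max(np.abs(model.beta))]
        for _ in range(6):
            model = local_train(model, X, y, epochs=10, lr=1e-6)
            norms.append(np.max(np.abs(model.beta)))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < norms[0]

    def test_objective_never_increases_across_slices(self, rng):
        X, y = make_regression(rng)
        model = make_model(np.zeros(X.shape[1]), lam=0.5)
        prev = wen_objective(model, X, y)
        for _ in range(20):
            model = local_train(model, X, y, epochs=20, lr=1e-4)
            obj = wen_objective(model, X, y)
            assert obj <= prev + 1e-9
            prev = obj

    def test_single_client_training_approaches_oracle(self, rng):
        X, y = make_regression(rng, n=80, P=12, collinear=False)
        w = rng.uniform(0, 1, 12)
        oracle = centralized_wen_oracle(X, y, w, 1.0, 0.8)
        model = make_model(np.zeros(12), lam=1.0, weights=w)
        for r in range(300):
            model = local_train(model, X, y, epochs=20, lr=1e-4)
        gap = wen_objective(model, X, y) / wen_objective(oracle, X, y) - 1
        assert 0 <= gap < 1e-4

    def test_invalid_lr_rejected(self, rng):
        X, y = make_regression(rng)
        with pytest.raises(ConfigurationError):
            local_train(make_model(np.zeros(X.shape[1])), X, y, 5, lr=0.0)


class TestFedAvg:
    def test_identical_models_are_fixed_point(self):
        m = make_model([1.0, -2.0], intercept=0.3)
        out = fedavg_aggregate({"a": m, "b": m}, {"a": 4, "b": 6})
        np.testing.assert_allclose(out.beta, m.beta, atol=1e-8)
        assert out.intercept == pytest.approx(0.3, abs=1e-8)

    def test_sample_size_weighted_mean(self):
        m0 = make_model([0.0])
        m2 = make_model([2.0])
        out = fedavg_aggregate({"a": m0, "b": m2}, {"a": 1, "b": 3})
        assert out.beta[0] == pytest.approx(1.5, abs=1e-8)  # (0*1 + 2*3)/4

    def test_matches_plaintext_weighted_mean(self, rng):
        models, sizes = {}, {}
        for i in range(5):
            models[f"c{i}"] = make_model(rng.standard_normal(6), intercept=float(rng.normal()))
            sizes[f"c{i}"] = int(rng.integers(5, 50))
        out = fedavg_aggregate(models, sizes)
        total = sum(sizes.values())
        plain = sum(models[c].beta * sizes[c] for c in models) / total
        plain_b = sum(models[c].intercept * sizes[c] for c in models) / total
        np.testing.assert_allclose(out.beta, plain, atol=1e-7)
        assert out.intercept == pytest.approx(plain_b, abs=1e-7)

    def test_permutation_invariance(self, rng):
        models = {f"c{i}": make_model(rng.standard_normal(4)) for i in range(4)}
        sizes = {f"c{i}": 10 + i for i in range(4)}
        a = fedavg_aggregate(models, sizes)
        rev = dict(reversed(list(models.items())))
        b = fedavg_aggregate(rev, sizes)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_provenance_mismatch_rejected(self):
        with pytest.raises(ProtocolError):
            fedavg_aggregate(
                {"a": make_model([1.0], lam=1.0), "b": make_model([1.0], lam=2.0)},
                {"a": 1, "b": 1},
            )


class TestFederatedTraining:
    def test_one_client_reproduces_centralized_trajectory_bitwise(self, rng):
        X, y = make_regression(rng, n=50, P=8)
        w = rng.uniform(0, 1, 8)
        schedule = TrainingSchedule(global_rounds=30, local_epochs=5)
        fed = train_federated_wen({"c0": (X, y)}, w, 0.7, 0.8, schedule)
        manual = make_model(np.zeros(8), lam=0.7, weights=w)
        for r in range(30):
            manual = local_train(manual, X, y, 5, schedule.lr_at(r))
        np.testing.assert_array_equal(fed.beta, manual.beta)
        assert fed.intercept == manual.intercept

    @pytest.mark.parametrize("n_clients", [2, 4])
    def test_partitioned_clients_near_centralized_optimum(self, n_clients, rng):
        X, y = make_regression(rng, n=120, P=15, collinear=False)
        w = rng.uniform(0, 1, 15)
        oracle_obj = wen_objective(centralized_wen_oracle(X, y, w, 1.0, 0.8), X, y)
        bounds = np.linspace(0, 120, n_clients + 1).astype(int)
        clients = {
            f"c{i}": (X[bounds[i] : bounds[i + 1]], y[bounds[i] : bounds[i + 1]])
            for i in range(n_clients)
        }
        fed = train_federated_wen(clients, w, 1.0, 0.8)
        fed_obj = wen_objective(fed, X, y)
        assert fed_obj >= oracle_obj - 1e-9
        assert (fed_obj - oracle_obj) / oracle_obj < 0.05

    def test_unweighted_unpenalized_converges_to_ols(self, rng):
        X, y = make_regression(rng, n=60, P=6, collinear=False)
        fed = train_federated_wen(
            {"c0": (X[:30], y[:30]), "c1": (X[30:], y[30:])},
            np.ones(6),
            lam=1e-12,
            alpha=0.8,
            schedule=TrainingSchedule(global_rounds=200, local_epochs=20),
        )
        A = np.column_stack([np.ones(60), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_obj = float(np.sum((y - A @ coef) ** 2))
        fed_obj = wen_objective(fed, X, y)
        assert (fed_obj - ols_obj) / ols_obj < 1e-3


class TestCentralizedOracle:
    def test_zero_weights_give_ols(self, rng):
        X, y = make_regression(rng, n=40, P=5, collinear=False)
        model = centralized_wen_oracle(X, y, np.zeros(5), 3.0, 0.8)
        A = np.column_stack([np.ones(40), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert model.intercept == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(model.beta, coef[1:], atol=1e-6)

    def test_orthonormal_design_closed_form(self, rng):
        """With centered orthonormal columns the coordinate solution is an
        explicit soft-threshold shrinkage."""
        n, P = 30, 5
        raw = rng.standard_normal((n, P))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = Q[:, :P]
        y = rng.standard_normal(n)
        w = rng.uniform(0, 1, P)
        lam, alpha = 0.8, 0.6
        model = centralized_wen_oracle(X, y, w, lam, alpha)
        q = X.T @ y
        expected = (
            np.sign(q) * np.maximum(2 * np.abs(q) - lam * alpha * w, 0.0)
        ) / (2.0 + lam * (1 - alpha) * w)
        np.testing.assert_allclose(model.beta, expected, atol=1e-8)
        assert model.intercept == pytest.approx(float(y.mean()), abs=1e-8)

    def test_kkt_residuals_vanish_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            P = int(rng.integers(3, 20))
            X, y = make_regression(rng, n=n, P=P)
            w = rng.uniform(0, 1, P)
            lam = float(10 ** rng.uniform(-2, 1.5))
            model = centralized_wen_oracle(X, y, w, lam, 0.8)
            assert kkt_residual(model, X, y) < 1e-8

    def test_raising_one_weight_weakly_shrinks_that_coordinate(self, rng):
        X, y = make_regression(rng, n=50, P=8)
        w = np.full(8, 0.3)
        base = centralized_wen_oracle(X, y, w, 2.0, 0.8)
        for j in (0, 3, 7):
            w2 = w.copy()
            w2[j] = 1.0
            bumped = centralized_wen_oracle(X, y, w2, 2.0, 0.8)
            assert abs(bumped.beta[j]) <= abs(base.beta[j]) + 1e-10


class TestEnLsBaseline:
    def test_full_support_equals_ols(self, rng):
        X = rng.standard_normal((80, 4))
        y = 2.0 + X @ np.array([1.0, -1.5, 0.8, 2.2]) + 0.05 * rng.standard_normal(80)
        model = en_ls_baseline(X, y, lam_grid=[1e-6, 1e-5], alpha=0.8)
        assert model.provenance["support_size"] == 4
        A = np.column_stack([np.ones(80), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.beta, coef[1:], atol=1e-6)

    def test_all_shrunk_gives_intercept_only_mean_model(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        model = en_ls_baseline(X, y, lam_grid=[1e9, 1e10], alpha=0.8)
        np.testing.assert_array_equal(model.beta, np.zeros(3))
        assert model.intercept == pytest.approx(float(y.mean()), abs=1e-9)
        np.testing.assert_allclose(predict(model, X), np.full(40, y.mean()), atol=1e-9)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            en_ls_baseline(np.zeros((5, 2)), np.zeros(5), lam_grid=[])


class TestPredict:
    def test_basic_contracts(self, rng):
        model = make_model(np.zeros(3), intercept=1.5)
        X = rng.standard_normal((4, 3))
        np.testing.assert_allclose(predict(model, X), np.full(4, 1.5))
        m2 = make_model([2.0, -1.0, 0.5])
        np.testing.assert_allclose(predict(m2, np.eye(3)), m2.beta)
        X3 = np.array([[1.0, 2.0], [3.0, 4.0], [0.5, -1.0]])
        m3 = make_model([2.0, -1.0], intercept=0.25)
        np.testing.assert_allclose(predict(m3, X3), X3 @ m3.beta + 0.25)
        with pytest.raises(ConfigurationError):
            predict(m3, np.zeros((2, 5)))
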