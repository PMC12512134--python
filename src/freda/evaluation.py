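"""Self-contained validation studies for the federated pipeline.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and returns summary numbers.  The studies back both the
acceptance checks in the test suite and ``scripts/acceptance.py``.

Desk-scale study sizes (chosen once; see docs/methods.md): the end-to-end
studies use the default generator conditions (P=100, pooled source n=80 in
four clients, 90 target samples in three groups) with an 8-point lambda grid
on [1e-2, 1e2]; the protocol-level studies use the sizes stated with each
function.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .datasets import (
    DomainDataset,
    default_shift_spec,
    generate_multidomain_dataset,
    horvath_inverse,
    partition_source,
)
from .gpr import centralized_gpr_oracle, optimize_local_hyperparams
from .masking import encode_matrix, generate_shared_mask, gram_from_encoded
from .pipeline import RunConfig, run_centralized_wenda, run_feature_models, run_freda
from .secure_agg import FixedPointCodec, derive_zero_sum_masks, pairwise_seeds_from, secure_sum
from .wen import (
    TrainingSchedule,
    centralized_wen_oracle,
    en_ls_baseline,
    kkt_residual,
    predict,
    train_federated_wen,
    wen_objective,
)

__all__ = [
    "DESK_LAMBDA_GRID",
    "IMBALANCE_SCHEMES",
    "gram_error_study",
    "secure_sum_study",
    "federation_transparency_study",
    "hyperparam_recovery_study",
    "shift_detection_study",
    "wen_kkt_study",
    "federated_gap_study",
    "degenerate_identity_study",
    "adaptation_gain_study",
]

DESK_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-2.0, 2.0, 8))

IMBALANCE_SCHEMES: dict[str, Sequence[float] | str] = {
    "uniform": "uniform",
    "skewed": (0.5, 0.2, 0.2, 0.1),
    "highly_skewed": (0.533, 0.266, 0.133, 0.068),
}


def _seed(base: int, *mix: int) -> int:
    return int(np.random.SeedSequence([int(base) & 0x7FFFFFFF, *mix]).generate_state(1)[0]) & 0x7FFFFFFF


def gram_error_study(seed: int, n_trials: int = 100) -> float:
    """Worst relative error of masked-path Gram matrices against plaintext
    products over random instances (n <= 50, P <= 30, d = P + 5)."""
    rng = np.random.default_rng(_seed(seed, 1))
    worst = 0.0
    for trial in range(n_trials):
        n = int(rng.integers(1, 51))
        m = int(rng.integers(1, 51))
        P = int(rng.integers(2, 31))
        bundle = generate_shared_mask(_seed(seed, 1, trial), P, P + 5, ["p", "q"])
        Xp = rng.standard_normal((n, P))
        Xq = rng.standard_normal((m, P))
        g = gram_from_encoded(encode_matrix(Xp, bundle, "p"), encode_matrix(Xq, bundle, "q"))
        plain = Xp @ Xq.T
        worst = max(worst, float(np.max(np.abs(g - plain)) / max(1.0, np.max(np.abs(plain)))))
    return worst


def secure_sum_study(seed: int, max_parties: int = 8) -> float:
    """Worst absolute deviation of secure sums from plaintext sums, in units
    of the codec bound 2^-frac_bits * n_parties."""
    rng = np.random.default_rng(_seed(seed, 2))
    codec = FixedPointCodec(frac_bits=32)
    worst_ratio = 0.0
    for n_parties in range(2, max_parties + 1):
        parties = [f"p{i}" for i in range(n_parties)]
        values = {p: rng.uniform(-10, 10, size=25) for p in parties}
        masks = derive_zero_sum_masks(
            parties, (25,), 0, pairwise_seeds_from(_seed(seed, 2, n_parties), parties)
        )
        out = secure_sum(values, codec, masks)
        err = float(np.max(np.abs(out - sum(values.values()))))
        worst_ratio = max(worst_ratio, err / (2.0**-32 * n_parties))
    return worst_ratio


def federation_transparency_study(
    seed: int,
    P: int = 50,
    n_source: int = 200,
    n_target: int = 60,
    client_counts: Sequence[int] = (2, 4, 8),
) -> dict[str, float]:
    """Max absolute gap between federated predictive means/variances and the
    pooled closed form, across client splits, at the federated
    hyper-parameters."""
    spec = default_shift_spec(seed=_seed(seed, 3), P=P, n_per_domain=n_source,
                              n_target=n_target)
    sources, target, _ = generate_multidomain_dataset(spec, 1)
    pooled = sources[0]
    gap_mean = gap_var = 0.0
    for n_clients in client_counts:
        parts = partition_source(pooled, n_clients, "uniform", seed=_seed(seed, 3, n_clients))
        results = run_feature_models(parts, target, RunConfig(seed=_seed(seed, 3, n_clients)))
        X_pool = np.vstack([p.X for p in parts])  # pooled in protocol client order
        for res in results:
            f = res.feature
            X_nf = np.delete(X_pool, f, axis=1)
            x_f = X_pool[:, f]
            Xt_nf = np.delete(target.X, f, axis=1)
            mean, var = centralized_gpr_oracle(X_nf, x_f, Xt_nf, res.hyper)
            gap_mean = max(gap_mean, float(np.max(np.abs(res.mean - mean))))
            gap_var = max(gap_var, float(np.max(np.abs(res.variance - var))))
    return {"mean_gap": gap_mean, "variance_gap": gap_var}


def hyperparam_recovery_study(
    seed: int,
    n: int = 200,
    n_features: int = 100,
    sigma_k2: float = 2.0,
    sigma_eps2: float = 0.5,
    n_seeds: int = 10,
) -> dict[str, float]:
    """Median relative recovery error of the kernel and noise variances on
    data simulated from the linear-kernel GP itself."""
    errs_k, errs_e = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(_seed(seed, 4, i))
        X = rng.standard_normal((n, n_features))
        cov = sigma_k2 * X @ X.T + sigma_eps2 * np.eye(n)
        y = rng.multivariate_normal(np.zeros(n), cov, method="cholesky")
        est = optimize_local_hyperparams(X, y)
        errs_k.append(abs(est.sigma_k2 - sigma_k2) / sigma_k2)
        errs_e.append(abs(est.sigma_eps2 - sigma_eps2) / sigma_eps2)
    return {
        "sigma_k2_median_rel_err": float(np.median(errs_k)),
        "sigma_eps2_median_rel_err": float(np.median(errs_e)),
    }


def shift_detection_study(seed: int, n_runs: int = 20, n_sources: int = 4) -> dict[str, float]:
    """Fraction of seeded runs in which perturbed features receive strictly
    higher mean penalty weights (and lower confidences) than stable ones."""
    from .pipeline import compute_group_weights

    weight_hits = conf_hits = 0
    for i in range(n_runs):
        spec = default_shift_spec(seed=_seed(seed, 5, i))
        sources, target, gt = generate_multidomain_dataset(spec, n_sources)
        cfg = RunConfig(seed=_seed(seed, 5, i))
        results = run_feature_models(sources, target, cfg)
        confidences, weights = compute_group_weights(results, target, cfg)
        pf = np.asarray(gt["perturbed_features"], dtype=int)
        w = np.mean([weights[g].values for g in weights], axis=0)
        c = np.mean([confidences[g].values for g in confidences], axis=0)
        assert np.all((c >= 0) & (c <= 1)) and np.all((w >= 0) & (w <= 1))
        if w[pf].mean() > np.delete(w, pf).mean():
            weight_hits += 1
        if c[pf].mean() < np.delete(c, pf).mean():
            conf_hits += 1
    return {
        "weight_detection_rate": weight_hits / n_runs,
        "confidence_detection_rate": conf_hits / n_runs,
    }


def wen_kkt_study(seed: int, n_instances: int = 20) -> float:
    """Worst KKT residual of the coordinate-descent oracle on random
    weighted-elastic-net instances."""
    rng = np.random.default_rng(_seed(seed, 6))
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(20, 100))
        P = int(rng.integers(3, 30))
        X = rng.standard_normal((n, P))
        y = 1.0 + X @ (rng.standard_normal(P) / np.sqrt(P)) + 0.3 * rng.standard_normal(n)
        w = rng.uniform(0, 1, P)
        lam = float(10.0 ** rng.uniform(-2, 1.5))
        model = centralized_wen_oracle(X, y, w, lam, 0.8)
        worst = max(worst, kkt_residual(model, X, y))
    return worst


def federated_gap_study(
    seed: int,
    n: int = 200,
    P: int = 50,
    lam: float = 1.0,
    client_counts: Sequence[int] = (1, 2, 4, 8),
) -> float:
    """Worst relative pooled-objective gap of FedAvg training (default
    schedule: 100 rounds x 20 epochs, lr 1e-4 -> 1e-5) against the
    coordinate-descent optimum."""
    rng = np.random.default_rng(_seed(seed, 7))
    X = rng.standard_normal((n, P))
    y = 1.0 + X @ (rng.standard_normal(P) / np.sqrt(P)) + 0.2 * rng.standard_normal(n)
    w = rng.uniform(0, 1, P)
    oracle_obj = wen_objective(centralized_wen_oracle(X, y, w, lam, 0.8), X, y)
    worst = 0.0
    for n_clients in client_counts:
        bounds = np.linspace(0, n, n_clients + 1).astype(int)
        clients = {
            f"c{i}": (X[bounds[i] : bounds[i + 1]], y[bounds[i] : bounds[i + 1]])
            for i in range(n_clients)
        }
        fed = train_federated_wen(clients, w, lam, 0.8, TrainingSchedule())
        gap = (wen_objective(fed, X, y) - oracle_obj) / oracle_obj
        worst = max(worst, float(gap))
    return worst


def degenerate_identity_study(seed: int) -> float:
    """Max absolute difference between the single-client federated pipeline's
    target predictions and the pooled non-federated path."""
    spec = default_shift_spec(seed=_seed(seed, 8), P=60, n_per_domain=60)
    sources, target, gt = generate_multidomain_dataset(spec, 1)
    cfg = RunConfig(seed=_seed(seed, 8), lambda_grid=DESK_LAMBDA_GRID)
    fed = run_freda(sources, target, cfg, ground_truth=gt)
    cen = run_centralized_wenda(sources, target, cfg, ground_truth=gt)
    return float(np.max(np.abs(fed.predictions - cen.predictions)))


def _enls_eval_mae(pooled_X, pooled_y, target: DomainDataset, y_target, fit_groups, seed: int):
    base = en_ls_baseline(pooled_X, pooled_y, DESK_LAMBDA_GRID, alpha=0.8, seed=seed)
    lo = np.log(1.0 / 21.0)
    pred_age = horvath_inverse(np.clip(predict(base, target.X), lo, None))
    err = np.abs(pred_age - horvath_inverse(np.asarray(y_target)))
    mask = ~np.isin(target.groups.astype(str), list(fit_groups))
    return float(err[mask].mean())


def adaptation_gain_study(
    seed: int,
    n_seeds: int = 20,
    schemes: Mapping[str, Sequence[float] | str] | None = None,
) -> dict[str, dict[str, float]]:
    """FREDA vs the non-adaptive en-ls baseline on planted-shift data, under
    uniform and imbalanced four-client source partitions.

    Returns, per scheme, the fraction of seeds where FREDA's held-out-group
    MAE beats en-ls, plus the mean MAEs (years)."""
    schemes = dict(IMBALANCE_SCHEMES if schemes is None else schemes)
    out: dict[str, dict[str, float]] = {}
    for name, proportions in schemes.items():
        wins = 0
        freda_maes, enls_maes = [], []
        for i in range(n_seeds):
            run_seed = _seed(seed, 9, i)
            spec = default_shift_spec(seed=run_seed, n_per_domain=80)
            pooled_sources, target, gt = generate_multidomain_dataset(spec, 1)
            parts = partition_source(pooled_sources[0], 4, proportions, seed=run_seed)
            cfg = RunConfig(seed=run_seed, lambda_grid=DESK_LAMBDA_GRID)
            report = run_freda(parts, target, cfg, ground_truth=gt)
            enls = _enls_eval_mae(
                pooled_sources[0].X,
                pooled_sources[0].y,
                target,
                gt["y_target"],
                report.fit_groups,
                seed=run_seed,
            )
            freda_maes.append(report.mae_eval)
            enls_maes.append(enls)
            wins += report.mae_eval < enls
        out[name] = {
            "win_rate": wins / n_seeds,
            "freda_mae_mean": float(np.mean(freda_maes)),
            "enls_mae_mean": float(np.mean(enls_maes)),
        }
    return out
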