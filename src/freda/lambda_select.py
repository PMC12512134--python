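"""Regularization-strength selection for the adaptive models.

Prior-knowledge path: the target client holds a similarity score per group
(tissue) and labels for a subset of its groups.  For each labeled group the
best lambda on a grid is found by MAE (in chronological years, after the
inverse age transform); a line of log10(lambda) on similarity is fitted and
used to predict lambda for the held-out groups, clipped to the grid range.

Similarity-free fallback: ordinary K-fold cross-validation on the source
side, with folds stratified within clients so every client contributes to
every fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datasets import DomainDataset, horvath_inverse
from .exceptions import ConfigurationError
from .wen import TrainingSchedule, WENModel, predict, train_federated_wen

__all__ = [
    "LambdaSimilarityModel",
    "default_lambda_grid",
    "split_target",
    "select_best_lambda",
    "fit_similarity_lambda_model",
    "predict_lambda",
    "cv_select_lambda",
]


def default_lambda_grid(n_points: int = 15, lo: float = 1e-3, hi: float = 1e2) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


@dataclass(frozen=True)
class LambdaSimilarityModel:
    """Least-squares line of log10(lambda) on domain similarity."""

    slope: float
    intercept: float
    scale: str = "log10-lambda"


def split_target(
    target: DomainDataset, fit_groups: Sequence[str]
) -> tuple[DomainDataset, DomainDataset]:
    """Partition the target data into the labeled-subset groups (X_t1) and
    the remainder (X_t2); disjoint and exhaustive."""
    if target.groups is None:
        raise ConfigurationError("target dataset has no group tags")
    fit_groups = list(fit_groups)
    if not fit_groups:
        raise ConfigurationError("fit_groups must be nonempty")
    present = set(np.unique(target.groups).astype(str))
    missing = [g for g in fit_groups if str(g) not in present]
    if missing:
        raise ConfigurationError(f"groups not present in target: {missing}")
    mask = np.isin(target.groups.astype(str), [str(g) for g in fit_groups])
    t1 = target.subset(np.flatnonzero(mask), domain_id=f"{target.domain_id}-t1")
    t2 = target.subset(np.flatnonzero(~mask), domain_id=f"{target.domain_id}-t2")
    return t1, t2


def select_best_lambda(
    models_per_lambda: Mapping[float, WENModel],
    X: np.ndarray,
    y_true: np.ndarray,
    adult_age: float = 20.0,
) -> float:
    """Grid argmin of MAE in chronological-age years; ties go to the smaller
    lambda.  ``y_true`` is in transformed-age space."""
    if not models_per_lambda:
        raise ConfigurationError("empty lambda grid")
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size == 0:
        raise ConfigurationError("no labeled samples for lambda selection")
    ages_true = horvath_inverse(y_true, adult_age)
    best_lam, best_mae = None, np.inf
    for lam in sorted(models_per_lambda):
        pred = predict(models_per_lambda[lam], X)
        lo = np.log(1.0 / (adult_age + 1.0))
        ages_pred = horvath_inverse(np.clip(pred, lo, None), adult_age)
        mae = float(np.mean(np.abs(ages_pred - ages_true)))
        if mae < best_mae - 1e-12:
            best_mae, best_lam = mae, lam
    return float(best_lam)


def fit_similarity_lambda_model(points: Sequence[tuple[float, float]]) -> LambdaSimilarityModel:
    """Fit log10(lambda) = slope * similarity + intercept by least squares."""
    points = list(points)
    if len(points) < 2:
        raise ConfigurationError("need at least two (similarity, lambda) points")
    s = np.array([p[0] for p in points], dtype=float)
    lam = np.array([p[1] for p in points], dtype=float)
    if np.any(lam <= 0):
        raise ConfigurationError("lambdas must be positive")
    if np.ptp(s) < 1e-12:
        raise ConfigurationError("similarity values are degenerate (all equal)")
    A = np.column_stack([s, np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(A, np.log10(lam), rcond=None)
    return LambdaSimilarityModel(slope=float(coef[0]), intercept=float(coef[1]))


def predict_lambda(
    model: LambdaSimilarityModel,
    similarity: float,
    grid_range: tuple[float, float] = (1e-3, 1e2),
) -> float:
    """Predicted lambda ``10^(slope*s + intercept)``, clipped to the grid."""
    if not np.isfinite(similarity):
        raise ConfigurationError("similarity must be finite")
    lam = 10.0 ** (model.slope * float(similarity) + model.intercept)
    return float(np.clip(lam, grid_range[0], grid_range[1]))


def cv_select_lambda(
    clients: Mapping[str, tuple[np.ndarray, np.ndarray]],
    weights: np.ndarray,
    grid: Sequence[float],
    folds: int = 5,
    alpha: float = 0.8,
    schedule: TrainingSchedule | None = None,
    adult_age: float = 20.0,
    seed: int = 0,
    pairwise_seeds=None,
) -> float:
    """Similarity-free fallback: lambda minimizing mean source-side CV MAE of
    the federated weighted elastic net, folds stratified within clients."""
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ConfigurationError("empty lambda grid")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCF]))
    fold_idx = {}
    for cid, (X, y) in clients.items():
        n = X.shape[0]
        if n < folds:
            raise ConfigurationError(f"client {cid!r} has fewer samples than folds")
        fold_idx[cid] = rng.permutation(np.arange(n) % folds)

    lo = np.log(1.0 / (adult_age + 1.0))
    mean_mae = {}
    for lam in grid:
        maes = []
        for f in range(folds):
            train = {
                cid: (X[fold_idx[cid] != f], y[fold_idx[cid] != f])
                for cid, (X, y) in clients.items()
            }
            model = train_federated_wen(
                train, weights, lam, alpha, schedule, pairwise_seeds=pairwise_seeds
            )
            errs = []
            for cid, (X, y) in clients.items():
                m = fold_idx[cid] == f
                pred = np.clip(predict(model, X[m]), lo, None)
                errs.append(
                    np.abs(horvath_inverse(pred, adult_age) - horvath_inverse(y[m], adult_age))
                )
            maes.append(float(np.concatenate(errs).mean()))
        mean_mae[lam] = float(np.mean(maes))
    best = min(grid, key=lambda lam: (mean_mae[lam], lam))
    return float(best)
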