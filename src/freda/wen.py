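"""Weighted elastic net: objective, federated training, oracle solver.

The model solves

    min_beta ||y - b - X beta||^2
             + lambda * [ alpha * sum_f w_f |beta_f|
                          + (1 - alpha)/2 * sum_f w_f beta_f^2 ]

with per-feature penalty weights ``w_f`` in [0, 1] supplied by the
adaptation stage (shifted features get w near 1, trusted features near 0).
The residual sum of squares is *unnormalized*; lambda is therefore on the
scale of the pooled RSS.  The intercept is unpenalized.

Three training paths share this objective:

* :func:`centralized_wen_oracle` — proximal coordinate descent with exact
  soft-thresholding; the reference solution (and the non-federated path).
* :func:`local_train` + :func:`fedavg_aggregate` /
  :func:`train_federated_wen` — full-batch proximal-gradient training on
  each client with sample-size-weighted secure model averaging (FedAvg).
* :func:`en_ls_baseline` — the non-adaptive baseline: an ordinary elastic
  net with cross-validated lambda followed by a least-squares refit on the
  selected support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, ProtocolError, TrainingError
from .secure_agg import FixedPointCodec, derive_zero_sum_masks, pairwise_seeds_from, secure_sum

__all__ = [
    "WENModel",
    "TrainingSchedule",
    "wen_objective",
    "local_train",
    "fedavg_aggregate",
    "train_federated_wen",
    "en_ls_baseline",
    "centralized_wen_oracle",
    "kkt_residual",
    "predict",
]


@dataclass
class WENModel:
    """Weighted-elastic-net coefficients with their (lambda, alpha, weights)
    provenance."""

    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.beta.shape != self.weights.shape:
            raise ConfigurationError("beta and weights must have equal length")
        if not np.isfinite(self.beta).all() or not np.isfinite(self.intercept):
            raise ConfigurationError("non-finite coefficients")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ConfigurationError("lambda must be nonnegative")


@dataclass(frozen=True)
class TrainingSchedule:
    """FedAvg schedule: global rounds of local full-batch epochs with an
    exponential learning-rate decay from ``lr_start`` to ``lr_end``."""

    global_rounds: int = 100
    local_epochs: int = 20
    lr_start: float = 1e-4
    lr_end: float = 1e-5

    def __post_init__(self) -> None:
        if self.global_rounds < 1 or self.local_epochs < 1:
            raise ConfigurationError("schedule counts must be positive")
        if not (0 < self.lr_end <= self.lr_start):
            raise ConfigurationError("require 0 < lr_end <= lr_start")

    def lr_at(self, round_index: int) -> float:
        if self.global_rounds == 1:
            return self.lr_start
        frac = round_index / (self.global_rounds - 1)
        return self.lr_start * (self.lr_end / self.lr_start) ** frac


class _SuffStats:
    """Per-client sufficient statistics; every gradient/objective evaluation
    is O(P^2) instead of O(n P)."""

    __slots__ = ("G", "q", "s", "n", "yty", "ysum", "n_samples")

    def __init__(self, X: np.ndarray, y: np.ndarray, rss_scale: float = 1.0):
        """``rss_scale`` rescales the RSS term (a client holding a share of
        the pooled data uses n_pool / n_local so that its local objective is
        an unbiased stand-in for the pooled one)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ConfigurationError("X and y disagree on sample count")
        self.n_samples = X.shape[0]
        self.G = rss_scale * (X.T @ X)
        self.q = rss_scale * (X.T @ y)
        self.s = rss_scale * X.sum(axis=0)
        self.n = rss_scale * X.shape[0]
        self.yty = rss_scale * float(y @ y)
        self.ysum = rss_scale * float(y.sum())

    def objective(self, beta, b, weights, lam, alpha) -> float:
        rss = (
            self.yty
            - 2.0 * b * self.ysum
            - 2.0 * float(beta @ self.q)
            + 2.0 * b * float(self.s @ beta)
            + float(beta @ self.G @ beta)
            + self.n * b * b
        )
        pen = lam * (
            alpha * float(weights @ np.abs(beta))
            + 0.5 * (1.0 - alpha) * float(weights @ beta**2)
        )
        return rss + pen

    def smooth_gradient(self, beta, b, weights, lam, alpha):
        """Gradient of the differentiable part (RSS + weighted ridge)."""
        resid_proj = self.G @ beta + b * self.s - self.q
        g_beta = 2.0 * resid_proj + lam * (1.0 - alpha) * weights * beta
        g_b = 2.0 * (float(self.s @ beta) + self.n * b - self.ysum)
        return g_beta, g_b


def wen_objective(model: WENModel, X: np.ndarray, y: np.ndarray) -> float:
    """Objective value of ``model`` on data ``(X, y)`` (RSS unnormalized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != model.beta.shape[0]:
        raise ConfigurationError("feature-count mismatch")
    resid = y - model.intercept - X @ model.beta
    pen = model.lam * (
        model.alpha * float(model.weights @ np.abs(model.beta))
        + 0.5 * (1.0 - model.alpha) * float(model.weights @ model.beta**2)
    )
    return float(resid @ resid) + pen


def _prox_gradient_epochs(stats: _SuffStats, model: WENModel, epochs: int, lr: float):
    """Forward-backward epochs: explicit gradient on the smooth part, exact
    soft-threshold on the weighted L1 part (monotone for lr below 1/L,
    unlike a raw sign-subgradient step which oscillates at large lambda)."""
    beta = model.beta.copy()
    b = model.intercept
    l1_step = lr * model.lam * model.alpha * model.weights
    for _ in range(epochs):
        g_beta, g_b = stats.smooth_gradient(beta, b, model.weights, model.lam, model.alpha)
        z = beta - lr * g_beta
        beta = np.sign(z) * np.maximum(np.abs(z) - l1_step, 0.0)
        b -= lr * g_b
    return beta, b


def _local_train_stats(
    model: WENModel, stats: _SuffStats, epochs: int, lr: float, max_halvings: int = 5
) -> WENModel:
    obj0 = stats.objective(model.beta, model.intercept, model.weights, model.lam, model.alpha)
    for _ in range(max_halvings + 1):
        beta, b = _prox_gradient_epochs(stats, model, epochs, lr)
        obj1 = stats.objective(beta, b, model.weights, model.lam, model.alpha)
        if np.isfinite(obj1) and obj1 <= obj0 + 1e-12 * max(1.0, abs(obj0)):
            return replace(model, beta=beta, intercept=float(b))
        lr *= 0.5
    raise TrainingError(
        f"local objective increased ({obj0:.6g} -> {obj1:.6g}) despite learning-rate backoff"
    )


def local_train(
    model: WENModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
    rss_scale: float = 1.0,
) -> WENModel:
    """Full-batch proximal-gradient epochs for one local slice; guaranteed
    not to increase the local objective (learning rate is halved up to 5
    times on a failed slice).  ``rss_scale`` lifts the local RSS onto the
    pooled scale during federated training."""
    if lr <= 0:
        raise ConfigurationError("lr must be positive")
    return _local_train_stats(model, _SuffStats(X, y, rss_scale), epochs, lr)


def _same_provenance(a: WENModel, b: WENModel) -> bool:
    return (
        a.lam == b.lam
        and a.alpha == b.alpha
        and a.weights.shape == b.weights.shape
        and np.array_equal(a.weights, b.weights)
    )


def fedavg_aggregate(
    models: Mapping[str, WENModel],
    n_i: Mapping[str, int],
    codec: FixedPointCodec | None = None,
    pairwise_seeds: Mapping | None = None,
    round_id: int = 0,
    recorder=None,
) -> WENModel:
    """Sample-size-weighted coefficient average, computed through the
    secure-sum path so the aggregator never sees an individual update."""
    if not models:
        raise ProtocolError("no models to aggregate")
    parties = sorted(models)
    ref = models[parties[0]]
    for p in parties[1:]:
        if not _same_provenance(ref, models[p]):
            raise ProtocolError("clients disagree on (lambda, alpha, weights) provenance")
    total_n = float(sum(n_i[p] for p in parties))
    contrib = {
        p: np.concatenate([models[p].beta, [models[p].intercept]]) * (n_i[p] / total_n)
        for p in parties
    }
    if len(parties) == 1:
        stacked = contrib[parties[0]]
        if recorder is not None:
            recorder(round_id, parties[0], "aggregator", "model-update", stacked)
    else:
        codec = codec or FixedPointCodec()
        if pairwise_seeds is None:
            pairwise_seeds = pairwise_seeds_from(0, parties)
        masks = derive_zero_sum_masks(
            parties, contrib[parties[0]].shape, round_id, pairwise_seeds
        )
        if recorder is not None:
            headroom = max(3, int(np.ceil(np.log2(max(len(parties), 2)))) + 1)
            with np.errstate(over="ignore"):
                for p in parties:
                    share = codec.encode(contrib[p], headroom=headroom) + masks[p]
                    recorder(round_id, p, "aggregator", "secure-sum-share", share)
        stacked = secure_sum(contrib, codec, masks)
    if recorder is not None:
        for p in parties:
            recorder(round_id, "aggregator", p, "global-model", stacked)
    return replace(ref, beta=stacked[:-1], intercept=float(stacked[-1]))


def train_federated_wen(
    clients: Mapping[str, tuple[np.ndarray, np.ndarray]],
    weights: np.ndarray,
    lam: float,
    alpha: float,
    schedule: TrainingSchedule | None = None,
    codec: FixedPointCodec | None = None,
    pairwise_seeds: Mapping | None = None,
    init: WENModel | None = None,
    recorder=None,
    round_offset: int = 0,
) -> WENModel:
    """FedAvg training of the weighted elastic net across labeled clients.

    Deterministic given client contents: clients are visited in sorted-id
    order and every aggregation runs through the fixed-point secure sum.
    """
    if not clients:
        raise ProtocolError("no clients")
    schedule = schedule or TrainingSchedule()
    weights = np.asarray(weights, dtype=float)
    parties = sorted(clients)
    raw_sizes = {p: np.asarray(clients[p][0]).shape[0] for p in parties}
    n_pool = sum(raw_sizes.values())
    # each client's local objective is an unbiased surrogate of the pooled
    # one: its RSS is scaled by n_pool / n_local, the penalty kept whole
    stats = {p: _SuffStats(*clients[p], rss_scale=n_pool / raw_sizes[p]) for p in parties}
    sizes = raw_sizes
    if pairwise_seeds is None and len(parties) > 1:
        pairwise_seeds = pairwise_seeds_from(0, parties)
    model = init or WENModel(
        beta=np.zeros(weights.shape[0]),
        intercept=0.0,
        lam=float(lam),
        alpha=float(alpha),
        weights=weights,
        provenance={"trainer": "fedavg", "schedule": tuple(vars(schedule).values())},
    )
    for r in range(schedule.global_rounds):
        lr = schedule.lr_at(r)
        locals_ = {
            p: _local_train_stats(model, stats[p], schedule.local_epochs, lr) for p in parties
        }
        model = fedavg_aggregate(
            locals_, sizes, codec, pairwise_seeds, round_id=round_offset + r, recorder=recorder
        )
    return model


def predict(model: WENModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.beta.shape[0]:
        raise ConfigurationError("feature-count mismatch in predict")
    return X @ model.beta + model.intercept


# ---------------------------------------------------------------------------
# Centralized oracle (proximal coordinate descent)


def centralized_wen_oracle(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> WENModel:
    """Exact weighted-elastic-net solution by cyclic coordinate descent.

    Coordinate update: soft-threshold at ``lam * alpha * w_j`` with curvature
    ``2 ||x_j||^2 + lam * (1 - alpha) * w_j``; exact zeros arise naturally.
    Converges to objective tolerance ``tol`` (relative).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n, P = X.shape
    if weights.shape != (P,):
        raise ConfigurationError("weights must have length P")
    G = X.T @ X
    q = X.T @ y
    s = X.sum(axis=0)
    stats = _SuffStats(X, y)

    beta = np.zeros(P)
    b = stats.ysum / n
    thresh = lam * alpha * weights
    curv = 2.0 * np.diag(G) + lam * (1.0 - alpha) * weights
    Gb = G @ beta
    for it in range(max_iter):
        for j in range(P):
            if curv[j] <= 0:
                continue
            rho = 2.0 * (q[j] - b * s[j] - Gb[j] + G[j, j] * beta[j])
            new = np.sign(rho) * max(abs(rho) - thresh[j], 0.0) / curv[j]
            delta = new - beta[j]
            if delta != 0.0:
                Gb += delta * G[:, j]
                beta[j] = new
        b = (stats.ysum - float(s @ beta)) / n
        # subgradient optimality residual, from the incrementally tracked Gb
        g_smooth = 2.0 * (Gb + b * s - q) + lam * (1.0 - alpha) * weights * beta
        active = beta != 0.0
        res = np.where(
            active,
            np.abs(g_smooth + thresh * np.sign(beta)),
            np.maximum(np.abs(g_smooth) - thresh, 0.0),
        )
        if float(res.max(initial=0.0)) <= max(tol, 1e-9):
            break
    else:
        raise TrainingError("coordinate descent did not converge within max_iter")
    return WENModel(
        beta=beta,
        intercept=float(b),
        lam=float(lam),
        alpha=float(alpha),
        weights=weights,
        provenance={"trainer": "coordinate-descent", "iterations": it + 1},
    )


def kkt_residual(model: WENModel, X: np.ndarray, y: np.ndarray) -> float:
    """Max violation of the subgradient optimality conditions at ``model``.

    Zero coordinates must satisfy ``|2 x_j^T r| <= lam * alpha * w_j``; active
    coordinates must have an exactly vanishing subgradient; the intercept
    gradient must vanish.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - model.intercept - X @ model.beta
    g_smooth = -2.0 * (X.T @ resid) + model.lam * (1.0 - model.alpha) * model.weights * model.beta
    thresh = model.lam * model.alpha * model.weights
    active = model.beta != 0.0
    res_active = np.abs(g_smooth[active] + thresh[active] * np.sign(model.beta[active]))
    res_zero = np.maximum(np.abs(g_smooth[~active]) - thresh[~active], 0.0)
    res_b = abs(-2.0 * float(resid.sum()))
    pieces = [res_b]
    if res_active.size:
        pieces.append(float(res_active.max()))
    if res_zero.size:
        pieces.append(float(res_zero.max()))
    return max(pieces)


# ---------------------------------------------------------------------------
# Non-adaptive baseline


def en_ls_baseline(
    X: np.ndarray,
    y: np.ndarray,
    lam_grid: Sequence[float],
    alpha: float = 0.8,
    cv: int = 10,
    seed: int = 0,
) -> WENModel:
    """Elastic net with CV-selected lambda followed by an OLS refit on the
    selected support (the classic non-adaptive epigenetic-clock baseline).

    The CV elastic-net fit maps exactly onto scikit-learn's parameterization
    via ``alpha_sklearn = lambda / (2 n)`` and ``l1_ratio = alpha``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_grid = np.asarray(sorted(lam_grid), dtype=float)
    if lam_grid.size == 0:
        raise ConfigurationError("empty lambda grid")
    n = X.shape[0]
    enet = ElasticNetCV(
        alphas=lam_grid / (2.0 * n),
        l1_ratio=float(alpha),
        cv=KFold(n_splits=cv, shuffle=True, random_state=seed),
        fit_intercept=True,
        max_iter=50_000,
    )
    with warnings.catch_warnings():
        # CV candidate fits at extreme grid ends may stop at a loose duality
        # gap; lambda selection is unaffected.
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(X, y)
    lam = float(enet.alpha_ * 2.0 * n)
    support = np.flatnonzero(enet.coef_)

    beta = np.zeros(X.shape[1])
    if support.size == 0:
        intercept = float(y.mean())
    else:
        A = np.column_stack([np.ones(n), X[:, support]])
        AtA, Aty = A.T @ A, A.T @ y
        try:
            coef = np.linalg.solve(AtA, Aty)
        except np.linalg.LinAlgError:
            coef = np.linalg.solve(AtA + 1e-8 * np.eye(A.shape[1]), Aty)
        intercept = float(coef[0])
        beta[support] = coef[1:]
    return WENModel(
        beta=beta,
        intercept=intercept,
        lam=lam,
        alpha=float(alpha),
        weights=np.ones(X.shape[1]),
        provenance={"method": "en-ls", "support_size": int(support.size)},
    )
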