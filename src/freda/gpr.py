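"""Per-feature Gaussian-process regression with a linear kernel.

Each feature f is modeled from all other features: training inputs are the
source rows with column f removed, training targets are the source values of
column f.  With the linear kernel ``k(A, B) = sigma_k^2 A B^T`` the predictive
distribution on target rows is closed form,

    mean = K* K^{-1} x_f,      cov = K** - K* K^{-1} K*^T,

with ``K = sigma_k^2 X X^T + sigma_eps^2 I``.  Only Gram matrices of the data
enter, which is what makes the masked-matrix-product federation exact: the
aggregator assembles the very same Gram blocks from encoded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .exceptions import NumericalError, ProtocolError
from .masking import RowMask, apply_row_mask, unmask_vector
from .secure_agg import FixedPointCodec, derive_zero_sum_masks, secure_sum

__all__ = [
    "GPRHyperparams",
    "FeatureModelResult",
    "neg_log_marginal_likelihood",
    "optimize_local_hyperparams",
    "aggregate_hyperparams",
    "assemble_kernel_matrices",
    "predicted_mean_protocol",
    "predicted_variance",
    "centralized_gpr_oracle",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_DEFAULT_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class GPRHyperparams:
    """Linear-kernel prior variance and observation-noise variance."""

    sigma_k2: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        for name, v in (("sigma_k2", self.sigma_k2), ("sigma_eps2", self.sigma_eps2)):
            if not np.isfinite(v) or v <= 0:
                raise NumericalError(f"{name} must be strictly positive and finite")


@dataclass
class FeatureModelResult:
    """Target-side predictive distribution of one feature model."""

    feature: int
    hyper: GPRHyperparams
    mean: np.ndarray  # length n_t
    variance: np.ndarray  # length n_t, latent (noise-free), clipped at 0

    def to_record(self) -> dict:
        return {
            "feature": int(self.feature),
            "sigma_k2": float(self.hyper.sigma_k2),
            "sigma_eps2": float(self.hyper.sigma_eps2),
            "mean": self.mean.tolist(),
            "variance": self.variance.tolist(),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "FeatureModelResult":
        return cls(
            feature=int(rec["feature"]),
            hyper=GPRHyperparams(rec["sigma_k2"], rec["sigma_eps2"]),
            mean=np.asarray(rec["mean"], dtype=float),
            variance=np.asarray(rec["variance"], dtype=float),
        )


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with an escalating jitter ladder (1e-8 * mean diag, x10, 3x)."""
    base = 1e-8 * float(np.mean(np.diag(K)))
    jitter = 0.0
    for attempt in range(4):
        try:
            return cho_factor(K + jitter * np.eye(K.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter = base * 10.0**attempt if base > 0 else 10.0 ** (attempt - 10)
    raise NumericalError("kernel matrix not positive definite after jitter escalation")


def _nll_and_grad(gram: np.ndarray, x_f: np.ndarray, log_theta: np.ndarray):
    """Negative log marginal likelihood and its gradient in log parameters.

    ``gram`` is ``X_nf X_nf^T``; working from the Gram matrix keeps every
    likelihood evaluation O(n^2) after one O(n^3) factorization.
    """
    sk2, se2 = np.exp(log_theta)
    n = gram.shape[0]
    K = sk2 * gram + se2 * np.eye(n)
    cf, _ = _chol_with_jitter(K)
    alpha = cho_solve(cf, x_f)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    nll = 0.5 * float(x_f @ alpha) + 0.5 * logdet + 0.5 * n * _LOG2PI
    Kinv = cho_solve(cf, np.eye(n))
    # d nll / d sk2 = 0.5 tr(K^-1 G) - 0.5 a^T G a ; chain rule for log scale
    g_sk2 = 0.5 * float(np.sum(Kinv * gram)) - 0.5 * float(alpha @ gram @ alpha)
    g_se2 = 0.5 * float(np.trace(Kinv)) - 0.5 * float(alpha @ alpha)
    return nll, np.array([g_sk2 * sk2, g_se2 * se2])


def neg_log_marginal_likelihood(
    X_nf: np.ndarray, x_f: np.ndarray, hyper: GPRHyperparams
) -> float:
    """-log p(x_f | X_nf, hyper) under the linear-kernel GP."""
    X_nf = np.atleast_2d(np.asarray(X_nf, dtype=float))
    x_f = np.asarray(x_f, dtype=float)
    if X_nf.shape[0] != x_f.shape[0]:
        raise NumericalError("X_nf and x_f disagree on sample count")
    if not (np.isfinite(X_nf).all() and np.isfinite(x_f).all()):
        raise NumericalError("non-finite inputs")
    gram = X_nf @ X_nf.T
    nll, _ = _nll_and_grad(gram, x_f, np.log([hyper.sigma_k2, hyper.sigma_eps2]))
    return nll


def optimize_local_hyperparams(
    X_nf: np.ndarray,
    x_f: np.ndarray,
    init: GPRHyperparams | None = None,
    bounds: tuple[float, float] = _DEFAULT_BOUNDS,
    n_restarts: int = 0,
    seed: int = 0,
) -> GPRHyperparams:
    """Maximize the local marginal likelihood over (sigma_k2, sigma_eps2).

    L-BFGS-B in log-parameter space with box bounds; the best point ever
    evaluated is returned, so the result is never worse than the init.
    """
    init = init or GPRHyperparams(1.0, 1.0)
    X_nf = np.atleast_2d(np.asarray(X_nf, dtype=float))
    x_f = np.asarray(x_f, dtype=float)
    gram = X_nf @ X_nf.T
    log_lo, log_hi = np.log(bounds[0]), np.log(bounds[1])

    best = {"nll": np.inf, "theta": np.log([init.sigma_k2, init.sigma_eps2])}

    def objective(log_theta):
        try:
            nll, grad = _nll_and_grad(gram, x_f, log_theta)
        except NumericalError:
            return np.inf, np.zeros(2)
        if nll < best["nll"]:
            best["nll"] = nll
            best["theta"] = log_theta.copy()
        return nll, grad

    starts = [np.log([init.sigma_k2, init.sigma_eps2])]
    if n_restarts:
        rng = np.random.default_rng(seed)
        starts += list(rng.uniform(log_lo, log_hi, size=(n_restarts, 2)))
    for x0 in starts:
        minimize(
            objective,
            np.clip(x0, log_lo, log_hi),
            jac=True,
            method="L-BFGS-B",
            bounds=[(log_lo, log_hi)] * 2,
        )
    objective(np.log([init.sigma_k2, init.sigma_eps2]))  # guarantee descent property
    theta = np.clip(best["theta"], log_lo, log_hi)
    return GPRHyperparams(float(np.exp(theta[0])), float(np.exp(theta[1])))


def aggregate_hyperparams(
    per_client: Mapping[str, GPRHyperparams],
    codec: FixedPointCodec | None = None,
    pairwise_seeds: Mapping | None = None,
    round_id: int = 0,
    sample_sizes: Mapping[str, int] | None = None,
) -> GPRHyperparams:
    """Global hyper-parameters as the mean of the clients' local optima,
    computed through the secure-aggregation path.

    Unweighted by default; pass ``sample_sizes`` for a sample-size-weighted
    variant.
    """
    if not per_client:
        raise ProtocolError("no clients to aggregate")
    codec = codec or FixedPointCodec()
    parties = sorted(per_client)
    if sample_sizes is None:
        contrib = {p: np.array([per_client[p].sigma_k2, per_client[p].sigma_eps2]) for p in parties}
        denom = float(len(parties))
    else:
        denom = float(sum(sample_sizes[p] for p in parties))
        contrib = {
            p: np.array([per_client[p].sigma_k2, per_client[p].sigma_eps2]) * sample_sizes[p]
            for p in parties
        }
    if len(parties) == 1:
        total = contrib[parties[0]]
    else:
        if pairwise_seeds is None:
            from .secure_agg import pairwise_seeds_from

            pairwise_seeds = pairwise_seeds_from(0, parties)
        masks = derive_zero_sum_masks(parties, (2,), round_id, pairwise_seeds)
        total = secure_sum(contrib, codec, masks)
    mean = total / denom
    return GPRHyperparams(float(mean[0]), float(mean[1]))


def assemble_kernel_matrices(
    gram_ss: np.ndarray,
    gram_ts: np.ndarray,
    gram_tt: np.ndarray,
    hyper: GPRHyperparams,
    n_S: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale Gram blocks into kernel matrices.

    ``K = sigma_k^2 G_ss + sigma_eps^2 I``, ``K* = sigma_k^2 G_ts`` (target x
    source), ``K** = sigma_k^2 G_tt`` (latent, no noise term).
    """
    gram_ss = np.asarray(gram_ss, dtype=float)
    if gram_ss.shape != (n_S, n_S):
        raise ProtocolError("gram_ss shape mismatch")
    if np.max(np.abs(gram_ss - gram_ss.T)) > 1e-8 * max(1.0, np.max(np.abs(gram_ss))):
        raise ProtocolError("gram_ss is not symmetric")
    K = hyper.sigma_k2 * gram_ss + hyper.sigma_eps2 * np.eye(n_S)
    K_star = hyper.sigma_k2 * np.asarray(gram_ts, dtype=float)
    K_star_star = hyper.sigma_k2 * np.asarray(gram_tt, dtype=float)
    return K, K_star, K_star_star


def predicted_mean_protocol(
    K_star: np.ndarray,
    K: np.ndarray,
    feature_columns: Mapping[str, np.ndarray],
    row_mask: RowMask,
    client_row_slices: Mapping[str, slice],
    recorder=None,
    round_id: int = 0,
) -> np.ndarray:
    """Masked protocol for the predictive mean ``K* K^{-1} X_f^S``.

    The aggregator computes ``B = K* K^{-1}`` and releases only the row-masked
    ``C B`` column blocks; each source client multiplies its block by its own
    feature column; the target client sums the contributions and removes the
    mask with ``C^{-1}``.  In exact arithmetic this equals the pooled product.
    """
    cf, _ = _chol_with_jitter(K)
    B = cho_solve(cf, np.asarray(K_star, dtype=float).T).T  # n_t x n_S
    B_masked = apply_row_mask(row_mask.C, B)

    n_S = K.shape[0]
    covered = np.zeros(n_S, dtype=bool)
    v = np.zeros(B.shape[0])
    for client in sorted(feature_columns):
        sl = client_row_slices[client]
        x_f = np.asarray(feature_columns[client], dtype=float)
        block = B_masked[:, sl]
        if block.shape[1] != x_f.shape[0]:
            raise ProtocolError(f"client {client!r}: slice width != feature column length")
        covered[sl] = True
        contrib = block @ x_f
        if recorder is not None:
            recorder(round_id, "aggregator", client, "masked-mean-block", block)
            recorder(round_id, client, "target", "masked-mean-contrib", contrib)
        v = v + contrib
    if not covered.all():
        raise ProtocolError("client row slices do not cover all source rows")
    return unmask_vector(row_mask.C_inv, v)


def predicted_variance(
    K_star_star: np.ndarray, K_star: np.ndarray, K: np.ndarray
) -> np.ndarray:
    """Diagonal of the latent predictive covariance ``K** - K* K^{-1} K*^T``,
    clipped at zero.  Only this diagonal is released to the target role."""
    cf, _ = _chol_with_jitter(K)
    sol = cho_solve(cf, np.asarray(K_star, dtype=float).T)  # n_S x n_t
    var = np.diag(np.asarray(K_star_star, dtype=float)) - np.sum(K_star * sol.T, axis=1)
    if np.min(var) < -1e-6 * max(1.0, float(np.max(np.abs(np.diag(K_star_star))))):
        raise NumericalError(f"predictive variance strongly negative ({np.min(var):.3e})")
    return np.clip(var, 0.0, None)


def centralized_gpr_oracle(
    X_source: np.ndarray,
    x_f: np.ndarray,
    X_target: np.ndarray,
    hyper: GPRHyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct pooled evaluation of the closed-form predictive distribution
    (test oracle for the federated protocol)."""
    X_source = np.atleast_2d(np.asarray(X_source, dtype=float))
    X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
    n_S = X_source.shape[0]
    K, K_star, K_star_star = assemble_kernel_matrices(
        X_source @ X_source.T, X_target @ X_source.T, X_target @ X_target.T, hyper, n_S
    )
    cf, _ = _chol_with_jitter(K)
    mean = K_star @ cho_solve(cf, np.asarray(x_f, dtype=float))
    var = predicted_variance(K_star_star, K_star, K)
    return mean, var
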