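"""Randomized-encoding masked matrix products and row masks.

All parties that hold data share a seed and derive a common mask matrix
``M`` (d x P, d > P, full column rank).  Each party computes a left inverse
``L_p`` with ``L_p M = I_P`` and ships its data as ``X_p L_p S`` where
``S = (M M^T)^{1/2}``.  Because ``S S^T = M M^T`` and ``L_p M = I``, the
aggregator can form exact cross-party Gram matrices

    (X_p L_p S)(X_q L_q S)^T = X_p (L_p M)(M^T L_q^T) X_q^T = X_p X_q^T

while each individual encoded matrix lives in a d-dimensional space that
hides both the raw values and the original dimensionality.

The row mask ``C`` (invertible n_t x n_t) hides the aggregator's intermediate
``K* K^{-1}`` from source clients during the predicted-mean protocol; the
target client undoes it with ``C^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GenerationError, ProtocolError

__all__ = [
    "MaskBundle",
    "EncodedMatrix",
    "RowMask",
    "generate_shared_mask",
    "encode_matrix",
    "gram_from_encoded",
    "make_row_mask",
    "apply_row_mask",
    "unmask_vector",
]

_MAX_RETRIES = 5


@dataclass
class MaskBundle:
    """Shared randomized-encoding keying material (never given to the
    aggregator role)."""

    seed: int
    P: int
    d: int
    M: np.ndarray
    S: np.ndarray
    left_inverses: dict[str, np.ndarray] = field(default_factory=dict)

    def left_inverse(self, party: str) -> np.ndarray:
        try:
            return self.left_inverses[party]
        except KeyError:
            raise ProtocolError(f"party {party!r} has no left inverse in this bundle")


@dataclass
class EncodedMatrix:
    values: np.ndarray  # n x d
    party: str
    bundle_tag: tuple[int, int, int] = (0, 0, 0)  # (seed, P, d) provenance

    @property
    def d(self) -> int:
        return self.values.shape[1]


def generate_shared_mask(
    seed: int,
    P: int,
    d: int,
    party_ids: list[str] | tuple[str, ...],
    randomize_left_inverses: bool = False,
) -> MaskBundle:
    """Deterministically derive the mask bundle all data-holding parties share.

    ``M`` has i.i.d. standard-normal entries (resampled up to 5 times if rank
    deficient), ``S`` is the symmetric PSD square root of ``M M^T`` via
    eigendecomposition, and the left inverse is the Moore-Penrose form
    ``(M^T M)^{-1} M^T``.  With ``randomize_left_inverses`` each party adds a
    private null-space component ``R_p (I - M L)``, which still satisfies
    ``L_p M = I``.
    """
    if d <= P:
        raise GenerationError("d must exceed P")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x3A5C]))
    M = None
    for _ in range(_MAX_RETRIES):
        cand = rng.standard_normal((d, P))
        if np.linalg.matrix_rank(cand) == P:
            M = cand
            break
    if M is None:
        raise GenerationError("could not draw a full-column-rank mask matrix")

    MMt = M @ M.T
    w, V = np.linalg.eigh(MMt)
    S = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T

    L = np.linalg.solve(M.T @ M, M.T)  # P x d, L M = I_P
    left_inverses = {}
    for party in sorted(party_ids):
        if randomize_left_inverses:
            R = rng.standard_normal((P, d))
            left_inverses[party] = L + R @ (np.eye(d) - M @ L)
        else:
            left_inverses[party] = L.copy()
    return MaskBundle(seed=int(seed), P=P, d=d, M=M, S=S, left_inverses=left_inverses)


def encode_matrix(X: np.ndarray, bundle: MaskBundle, party: str) -> EncodedMatrix:
    """Mask a party's raw matrix: ``X L_party S`` (n x d)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != bundle.P:
        raise ProtocolError(f"X must have {bundle.P} columns, got shape {X.shape}")
    values = X @ bundle.left_inverse(party) @ bundle.S
    return EncodedMatrix(values=values, party=party, bundle_tag=(bundle.seed, bundle.P, bundle.d))


def gram_from_encoded(A: EncodedMatrix, B: EncodedMatrix) -> np.ndarray:
    """Cross-party Gram matrix ``X_p X_q^T`` recovered from encodings only."""
    if A.bundle_tag != B.bundle_tag:
        raise ProtocolError("encoded matrices come from different mask bundles")
    if A.d != B.d:
        raise ProtocolError("encoded dimensionality mismatch")
    return A.values @ B.values.T


@dataclass
class RowMask:
    C: np.ndarray
    C_inv: np.ndarray

    @property
    def n(self) -> int:
        return self.C.shape[0]


def make_row_mask(n_t: int, seed: int, max_cond: float = 1e8) -> RowMask:
    """Random invertible n_t x n_t mask with a bounded condition number."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0]))
    for _ in range(_MAX_RETRIES):
        C = rng.standard_normal((n_t, n_t))
        if np.linalg.cond(C) < max_cond:
            return RowMask(C=C, C_inv=np.linalg.inv(C))
    raise GenerationError("could not draw a well-conditioned row mask")


def apply_row_mask(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.asarray(C) @ np.asarray(B)


def unmask_vector(C_inv: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.asarray(C_inv) @ np.asarray(v)
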