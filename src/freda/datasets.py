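"""Synthetic multi-domain regression data with controllable covariate shift.

The generator emulates the structure the federated pipeline is built for:
several labeled *source* domains and one unlabeled *target* domain that share
a linear inter-feature dependency structure (a low-rank latent factor model
``X = Z W + eps``), with a chosen subset of target features whose factor
loadings are rotated away from the source loadings.  Rotating loadings breaks
the cross-feature dependencies the per-feature regressors learn on the source
side, which is exactly the kind of covariate shift the adaptive weighting is
meant to detect, while leaving each feature's marginal scale roughly intact.

Labels follow a linear model ``y = X beta + nu`` in *transformed-age* space
(see :func:`horvath_transform`); ``beta`` is supported on unshifted features
so that a well-adapted model can generalize across the shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "DomainDataset",
    "ShiftSpec",
    "default_shift_spec",
    "generate_multidomain_dataset",
    "horvath_transform",
    "horvath_inverse",
    "partition_source",
    "read_domain_csv",
    "write_domain_csv",
]

LABEL_COL = "__label__"
GROUP_COL = "__group__"


@dataclass
class DomainDataset:
    """One party's data: a samples x features matrix plus optional labels
    and per-sample group (tissue) tags."""

    X: np.ndarray
    y: np.ndarray | None = None
    groups: np.ndarray | None = None
    domain_id: str = "domain"
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ConfigurationError("X must be 2-D (samples x features)")
        if not np.isfinite(self.X).all():
            raise ConfigurationError(f"{self.domain_id}: X contains non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.n,):
                raise ConfigurationError(f"{self.domain_id}: len(y) != n")
            if not np.isfinite(self.y).all():
                raise ConfigurationError(f"{self.domain_id}: y contains non-finite values")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (self.n,):
                raise ConfigurationError(f"{self.domain_id}: len(groups) != n")
        if self.feature_names is not None:
            self.feature_names = tuple(self.feature_names)
            if len(self.feature_names) != self.p:
                raise ConfigurationError(f"{self.domain_id}: feature name count != P")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray, domain_id: str | None = None) -> "DomainDataset":
        return DomainDataset(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            groups=None if self.groups is None else self.groups[idx],
            domain_id=domain_id or self.domain_id,
            feature_names=self.feature_names,
        )

    def without_labels(self) -> "DomainDataset":
        return replace(self, y=None)


@dataclass(frozen=True)
class ShiftSpec:
    """Parameters of the multi-domain generator.

    ``perturbed_features`` are 0-based column indices whose target-side factor
    loadings are rotated with magnitude ``shift_strength`` (0 means no shift).
    ``group_shift_scale`` scales that magnitude per target group, emulating
    tissues at different distances from the source domain; the implied
    similarity score of group g is ``1 / (1 + shift_strength * scale_g)``.
    """

    P: int
    n_per_domain: int
    latent_rank: int
    perturbed_features: tuple[int, ...]
    shift_strength: float
    noise_sd: float
    beta_true: tuple[float, ...]
    seed: int
    n_target: int = 90
    target_groups: int = 3
    group_shift_scale: tuple[float, ...] = (1.0, 0.5, 0.25)
    label_noise_sd: float = 0.2
    y_offset: float = 1.0

    def validate(self) -> None:
        if self.P <= 0 or self.n_per_domain <= 0 or self.n_target <= 0:
            raise ConfigurationError("P, n_per_domain and n_target must be positive")
        if not (0 < self.latent_rank < self.P):
            raise ConfigurationError("latent_rank must satisfy 0 < rank < P")
        if any(f < 0 or f >= self.P for f in self.perturbed_features):
            raise ConfigurationError("perturbed_features must be subset of 0..P-1")
        if self.shift_strength < 0:
            raise ConfigurationError("shift_strength must be nonnegative")
        if self.noise_sd <= 0 or self.label_noise_sd < 0:
            raise ConfigurationError("noise scales must be positive")
        if len(self.beta_true) != self.P:
            raise ConfigurationError("beta_true must have length P")
        if len(self.group_shift_scale) != self.target_groups:
            raise ConfigurationError("group_shift_scale must have one entry per target group")


def default_shift_spec(
    seed: int = 0,
    P: int = 100,
    latent_rank: int = 6,
    n_per_domain: int = 20,
    n_target: int = 90,
    n_perturbed: int = 20,
    shift_strength: float = 3.0,
    noise_sd: float = 0.1,
) -> ShiftSpec:
    """Standard study conditions: high-dimensional small-n data (pooled
    source n below P), strongly collinear features (rank ``latent_rank``
    << P), a minority of features shifted, labels supported on the stable
    features with unit-scale variability."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A]))
    n_perturbed = min(n_perturbed, max(1, P // 5))  # shifted minority of features
    perturbed = tuple(range(n_perturbed))
    stable = [f for f in range(P) if f not in perturbed]
    support = rng.choice(stable, size=min(10, len(stable)), replace=False).astype(int)
    beta = np.zeros(P)
    beta[support] = rng.normal(0.0, 1.0, size=len(support))
    # Feature marginal variance is ~1 by construction; scale beta so that
    # sd(y) ~ 1 in transformed-age units.
    beta /= np.linalg.norm(beta) + 1e-12
    return ShiftSpec(
        P=P,
        n_per_domain=n_per_domain,
        latent_rank=latent_rank,
        perturbed_features=perturbed,
        shift_strength=shift_strength,
        noise_sd=noise_sd,
        beta_true=tuple(beta),
        seed=int(seed),
        n_target=n_target,
    )


def _draw_X(rng: np.random.Generator, n: int, W: np.ndarray, noise_sd: float) -> np.ndarray:
    rank = W.shape[0]
    Z = rng.standard_normal((n, rank))
    return Z @ W + noise_sd * rng.standard_normal((n, W.shape[1]))


def _shift_loadings(
    rng: np.random.Generator, W: np.ndarray, features: Sequence[int], magnitude: float
) -> np.ndarray:
    """Rotate the loading vectors of the given feature columns while keeping
    their norms (marginal variances) unchanged."""
    W_t = W.copy()
    for f in features:
        w = W[:, f]
        u = rng.standard_normal(W.shape[0])
        v = w + magnitude * u
        nv = np.linalg.norm(v)
        if nv < 1e-12:  # pathological draw; keep direction
            continue
        W_t[:, f] = v * (np.linalg.norm(w) / nv)
    return W_t


def generate_multidomain_dataset(
    spec: ShiftSpec, n_sources: int
) -> tuple[list[DomainDataset], DomainDataset, dict]:
    """Generate labeled source domains and one unlabeled target domain.

    Returns ``(sources, target, ground_truth)``.  The target dataset carries
    group tags but *no* labels; the held-out target labels, the true
    coefficients, the loadings and the per-group similarity scores live only
    in the ground-truth record so that unsupervised stages cannot touch them.
    """
    spec.validate()
    if n_sources <= 0:
        raise ConfigurationError("n_sources must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xF2EDA]))
    P, rank = spec.P, spec.latent_rank
    beta = np.asarray(spec.beta_true, dtype=float)
    feature_names = tuple(f"f{j}" for j in range(P))

    W = rng.standard_normal((rank, P)) / np.sqrt(rank)

    sources = []
    for i in range(n_sources):
        X = _draw_X(rng, spec.n_per_domain, W, spec.noise_sd)
        y = spec.y_offset + X @ beta + spec.label_noise_sd * rng.standard_normal(spec.n_per_domain)
        y = np.maximum(y, horvath_transform(0.0) + 1e-9)
        sources.append(
            DomainDataset(X, y, None, domain_id=f"source{i}", feature_names=feature_names)
        )

    # Target: per-group rotated loadings for the perturbed features.
    G = spec.target_groups
    sizes = _largest_remainder_sizes(spec.n_target, np.full(G, 1.0 / G))
    X_parts, y_parts, g_parts, similarities = [], [], [], {}
    for g in range(G):
        mag = spec.shift_strength * spec.group_shift_scale[g]
        W_g = _shift_loadings(rng, W, spec.perturbed_features, mag)
        Xg = _draw_X(rng, sizes[g], W_g, spec.noise_sd)
        yg = spec.y_offset + Xg @ beta + spec.label_noise_sd * rng.standard_normal(sizes[g])
        yg = np.maximum(yg, horvath_transform(0.0) + 1e-9)
        name = f"g{g}"
        X_parts.append(Xg)
        y_parts.append(yg)
        g_parts.append(np.full(sizes[g], name, dtype=object))
        similarities[name] = 1.0 / (1.0 + mag)

    target = DomainDataset(
        np.vstack(X_parts),
        y=None,
        groups=np.concatenate(g_parts),
        domain_id="target",
        feature_names=feature_names,
    )
    ground_truth = {
        "y_target": np.concatenate(y_parts),
        "beta_true": beta,
        "W": W,
        "perturbed_features": list(spec.perturbed_features),
        "similarity": similarities,
        "group_sizes": {f"g{g}": int(sizes[g]) for g in range(G)},
    }
    return sources, target, ground_truth


# ---------------------------------------------------------------------------
# Age transform


def horvath_transform(age, adult_age: float = 20.0):
    """Log-linear age transform used by epigenetic clocks: logarithmic below
    the adult threshold, linear above it, continuous and strictly increasing.

    ``log((age+1)/(adult_age+1))`` for ``age <= adult_age``, else
    ``(age - adult_age)/(adult_age + 1)``.
    """
    age = np.asarray(age, dtype=float)
    if adult_age <= 0:
        raise ConfigurationError("adult_age must be positive")
    if np.any(age < 0):
        raise ConfigurationError("age must be nonnegative")
    out = np.where(
        age <= adult_age,
        np.log((age + 1.0) / (adult_age + 1.0)),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def horvath_inverse(t, adult_age: float = 20.0):
    """Inverse of :func:`horvath_transform` (needed to report errors in
    chronological years)."""
    t = np.asarray(t, dtype=float)
    if adult_age <= 0:
        raise ConfigurationError("adult_age must be positive")
    lo = np.log(1.0 / (adult_age + 1.0))
    if np.any(t < lo - 1e-12):
        raise ConfigurationError("t below the image of the age transform")
    out = np.where(
        t <= 0,
        (adult_age + 1.0) * np.exp(np.minimum(t, 0.0)) - 1.0,
        adult_age + t * (adult_age + 1.0),
    )
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Partitioning


def _largest_remainder_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    shares = proportions * n
    sizes = np.floor(shares).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(shares - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes


def partition_source(
    data: DomainDataset,
    n_clients: int,
    proportions: Sequence[float] | str = "uniform",
    seed: int = 0,
) -> list[DomainDataset]:
    """Split one pooled source dataset into per-client datasets.

    Samples are assigned uniformly at random (group tags are ignored when
    splitting); sizes follow the floored proportions with remainders going to
    the largest fractional parts.
    """
    if isinstance(proportions, str):
        if proportions != "uniform":
            raise ConfigurationError(f"unknown proportions keyword {proportions!r}")
        props = np.full(n_clients, 1.0 / n_clients)
    else:
        props = np.asarray(proportions, dtype=float)
        if len(props) != n_clients:
            raise ConfigurationError("n_clients must equal len(proportions)")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("proportions must sum to 1")
    if n_clients > data.n:
        raise ConfigurationError("more clients than samples")
    sizes = _largest_remainder_sizes(data.n, props)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5917]))
    perm = rng.permutation(data.n)
    parts, start = [], 0
    for i, size in enumerate(sizes):
        idx = np.sort(perm[start : start + size])
        parts.append(data.subset(idx, domain_id=f"{data.domain_id}-part{i}"))
        start += size
    return parts


# ---------------------------------------------------------------------------
# CSV / JSON round trips


def write_domain_csv(data: DomainDataset, path: str | Path) -> None:
    names = data.feature_names or tuple(f"f{j}" for j in range(data.p))
    df = pd.DataFrame(data.X, columns=list(names))
    if data.y is not None:
        df[LABEL_COL] = data.y
    if data.groups is not None:
        df[GROUP_COL] = data.groups
    df.to_csv(path, index=False)


def read_domain_csv(path: str | Path, domain_id: str | None = None) -> DomainDataset:
    path = Path(path)
    df = pd.read_csv(path)
    y = df.pop(LABEL_COL).to_numpy() if LABEL_COL in df else None
    groups = df.pop(GROUP_COL).to_numpy() if GROUP_COL in df else None
    return DomainDataset(
        df.to_numpy(dtype=float),
        y=y,
        groups=groups,
        domain_id=domain_id or path.stem,
        feature_names=tuple(df.columns),
    )


def write_ground_truth(gt: dict, path: str | Path) -> None:
    enc = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in gt.items()
    }
    Path(path).write_text(json.dumps(enc, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    gt = json.loads(Path(path).read_text())
    for k in ("y_target", "beta_true", "W"):
        if k in gt:
            gt[k] = np.asarray(gt[k], dtype=float)
    return gt
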