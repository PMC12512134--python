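"""Confidence scores and elastic-net penalty weights.

A feature whose target-side observations look typical under the
source-trained predictive distribution gets confidence near 1 and is barely
penalized; a feature whose dependencies shifted gets confidence near 0 and a
penalty weight near 1.  The score is the two-sided normal tail probability

    c = 2 * Phi(-|x - mu| / sigma),

i.e. the probability of a deviation at least as extreme as the observed one.
(The source formulation is sometimes written without the negation, which
would land in [1, 2]; the tail form is the meaningful one and is what we
implement.)  Weights are ``w = (1 - c)^k`` with ``k > 0`` sharpening the
contrast between trusted and shifted features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import ConfigurationError

__all__ = [
    "ConfidenceVector",
    "FeatureWeightVector",
    "confidence_score",
    "aggregate_confidence",
    "compute_feature_weights",
]

SIGMA_FLOOR = 1e-12


@dataclass
class ConfidenceVector:
    """Per-feature mean confidences for one target group."""

    group: str
    values: np.ndarray  # length P, entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ConfigurationError("confidences must lie in [0, 1]")


@dataclass
class FeatureWeightVector:
    """Per-feature elastic-net penalty weights ``(1 - c)^k`` for one group."""

    group: str
    values: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ConfigurationError("weights must lie in [0, 1]")


def confidence_score(x_obs, mu, sigma):
    """Two-sided tail probability of the observed deviation; 1 at zero
    deviation, strictly decreasing in |x - mu| / sigma.  Vectorized."""
    x_obs = np.asarray(x_obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (np.isfinite(x_obs).all() and np.isfinite(mu).all() and np.isfinite(sigma).all()):
        raise ConfigurationError("non-finite inputs to confidence_score")
    if np.any(sigma < 0):
        raise ConfigurationError("sigma must be nonnegative")
    z = np.abs(x_obs - mu) / np.maximum(sigma, SIGMA_FLOOR)
    c = 2.0 * norm.cdf(-z)
    c = np.clip(c, 0.0, 1.0)
    return float(c) if c.ndim == 0 else c


def aggregate_confidence(per_sample: np.ndarray, group_labels=None) -> dict[str, float]:
    """Mean confidence per group (a single "all" group when labels absent)."""
    per_sample = np.asarray(per_sample, dtype=float)
    if per_sample.size == 0:
        raise ConfigurationError("empty confidence vector")
    if group_labels is None:
        return {"all": float(per_sample.mean())}
    group_labels = np.asarray(group_labels)
    if group_labels.shape[0] != per_sample.shape[0]:
        raise ConfigurationError("group labels length mismatch")
    out = {}
    for g in np.unique(group_labels):
        mask = group_labels == g
        if not mask.any():
            raise ConfigurationError(f"empty group {g!r}")
        out[str(g)] = float(per_sample[mask].mean())
    return out


def compute_feature_weights(conf: ConfidenceVector, k: float) -> FeatureWeightVector:
    """``w_f = (1 - c_f)^k``: high-confidence features are penalized least,
    and larger k drives their penalties toward zero faster."""
    if not (np.isfinite(k) and k > 0):
        raise ConfigurationError("k must be a positive real")
    return FeatureWeightVector(group=conf.group, values=(1.0 - conf.values) ** k, k=float(k))
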