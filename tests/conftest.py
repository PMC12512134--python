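import numpy as np
import pytest

from freda.datasets import DomainDataset, ShiftSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_latent_data(rng, n, P, rank=4, noise_sd=0.1):
    """Low-rank-plus-noise matrix matching the generator's dependency model."""
    W = rng.standard_normal((rank, P)) / np.sqrt(rank)
    Z = rng.standard_normal((n, rank))
    return Z @ W + noise_sd * rng.standard_normal((n, P))


def tiny_spec(seed=0, **overrides) -> ShiftSpec:
    """A small, fast generator spec used by unit tests (not the study
    defaults)."""
    P = overrides.pop("P", 12)
    rng = np.random.default_rng(seed + 1)
    beta = np.zeros(P)
    beta[-4:] = rng.normal(0, 1, 4)
    beta /= np.linalg.norm(beta)
    base = dict(
        P=P,
        n_per_domain=25,
        latent_rank=3,
        perturbed_features=(0, 1, 2),
        shift_strength=3.0,
        noise_sd=0.1,
        beta_true=tuple(beta),
        seed=seed,
        n_target=30,
        target_groups=3,
    )
    base.update(overrides)
    return ShiftSpec(**base)


@pytest.fixture
def labeled_dataset(rng) -> DomainDataset:
    X = make_latent_data(rng, 30, 8)
    y = X @ np.linspace(-0.5, 0.5, 8) + 0.1 * rng.standard_normal(30)
    return DomainDataset(X, y, None, domain_id="unit-source")
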