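"""Secure aggregation by pairwise zero-sum masking over a fixed-point ring.

Every unordered pair of parties shares a seed; in each round the pair draws
the same pseudo-random tensor, one party adds it and the other subtracts it
(modulo 2**64), so the element-wise sum of all masks is exactly the zero
tensor.  Real values are carried as fixed-point integers so that the
cancellation is *exact*, not merely up to float rounding: an aggregator that
only ever sees masked contributions still recovers the true sum at codec
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ProtocolError

__all__ = ["FixedPointCodec", "derive_zero_sum_masks", "secure_sum", "pairwise_seeds_from"]

_U64 = np.uint64


@dataclass(frozen=True)
class FixedPointCodec:
    """Two's-complement fixed-point encoding with ``frac_bits`` fractional
    bits in a ring of size ``modulus`` (a power of two, default 2**64)."""

    frac_bits: int = 32
    modulus: int = 2**64

    def __post_init__(self) -> None:
        if self.modulus != 2**64:
            raise ProtocolError("only the native 64-bit ring is supported")
        if not (0 < self.frac_bits < 62):
            raise ProtocolError("frac_bits out of range")

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.frac_bits)

    def encode(self, values: np.ndarray, headroom: int = 8) -> np.ndarray:
        """Encode floats to ring elements. ``headroom`` reserves bits for
        sums of up to 2**headroom parties without overflow."""
        values = np.asarray(values, dtype=float)
        limit = 2.0 ** (63 - self.frac_bits - headroom)
        if not np.isfinite(values).all() or np.any(np.abs(values) >= limit):
            raise ProtocolError(
                f"value magnitude exceeds fixed-point range (|v| must be < {limit:g})"
            )
        q = np.rint(values * 2.0**self.frac_bits).astype(np.int64)
        return q.astype(_U64)

    def decode(self, ring_values: np.ndarray) -> np.ndarray:
        signed = np.asarray(ring_values, dtype=_U64).astype(np.int64)
        return signed.astype(float) * self.resolution


def pairwise_seeds_from(master_seed: int, party_ids: Iterable[str]) -> dict[frozenset, int]:
    """Derive one shared seed per unordered party pair from a master seed the
    aggregator never learns."""
    ids = sorted(party_ids)
    seeds = {}
    for i, p in enumerate(ids):
        for j in range(i + 1, len(ids)):
            ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, i, j])
            seeds[frozenset((p, ids[j]))] = int(ss.generate_state(1)[0])
    return seeds


def derive_zero_sum_masks(
    party_ids: Iterable[str],
    shape: tuple[int, ...],
    round_id: int,
    pairwise_seeds: Mapping[frozenset, int],
) -> dict[str, np.ndarray]:
    """Per-party additive masks over the 64-bit ring that sum to exactly zero.

    Masks are a deterministic function of the pairwise seeds and ``round_id``
    so each aggregation round uses a fresh stream.
    """
    ids = sorted(set(party_ids))
    if len(ids) == 0:
        raise ProtocolError("no parties")
    size = int(np.prod(shape)) if shape else 1
    masks = {p: np.zeros(shape, dtype=_U64) for p in ids}
    for i, p in enumerate(ids):
        for q in ids[i + 1 :]:
            key = frozenset((p, q))
            if key not in pairwise_seeds:
                raise ProtocolError(f"missing pairwise seed for {sorted(key)}")
            rng = np.random.default_rng(
                np.random.SeedSequence([pairwise_seeds[key] & 0x7FFFFFFF, int(round_id)])
            )
            r = rng.integers(0, 2**64, size=size, dtype=_U64).reshape(shape)
            with np.errstate(over="ignore"):
                masks[p] = masks[p] + r  # uint64 wrap-around is the ring addition
                masks[q] = masks[q] - r
    return masks


def secure_sum(
    local_values: Mapping[str, np.ndarray],
    codec: FixedPointCodec,
    masks: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Sum the parties' tensors without the aggregator ever seeing a raw one.

    Each party encodes and masks locally; only masked ring elements cross the
    trust boundary.  Equals the plain sum exactly at codec resolution.
    """
    if not local_values:
        raise ProtocolError("secure_sum of no parties")
    shapes = {np.asarray(v).shape for v in local_values.values()}
    if len(shapes) != 1:
        raise ProtocolError("all parties must contribute the same shape")
    headroom = max(3, int(np.ceil(np.log2(max(len(local_values), 2)))) + 1)
    total = None
    with np.errstate(over="ignore"):
        for party, value in local_values.items():
            masked = codec.encode(value, headroom=headroom) + np.asarray(masks[party], dtype=_U64)
            total = masked if total is None else total + masked
    return codec.decode(total)
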