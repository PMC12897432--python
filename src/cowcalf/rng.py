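"""Random-number management.

Two kinds of streams are provided:

* :func:`spawn_rng` — ordinary sequential :class:`numpy.random.Generator`
  streams, derived from a base seed and a text label.  Used for herd
  initialization, analysis bootstraps and anywhere a conventional stream is
  convenient.

* :class:`CounterRNG` — a counter-based (hash) generator.  Every draw is a
  pure function of ``(seed, *integer keys)``; there is no sequential state.
  The simulation engine keys each draw by (herd, animal id, day, purpose),
  which makes a herd's trajectory a deterministic function of its scenario
  seed alone, independent of how many herds are simulated alongside it and
  of the order in which events are processed.
"""

from __future__ import annotations

import hashlib
from enum import IntEnum

import numpy as np
from scipy.special import ndtri

__all__ = ["spawn_rng", "CounterRNG", "Purpose"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)


class Purpose(IntEnum):
    """Draw purposes; folded into the counter key so streams never collide."""

    GENOTYPE_MSBW = 1
    GENOTYPE_MILK = 2
    INIT_AGE = 3
    INIT_CONCEPTION = 4
    BIRTH_WEIGHT = 5
    CALF_SEX = 6
    CALF_DEATH = 7
    PPI = 8
    CONCEPTION = 9
    PREGNANCY_LOSS = 10
    ABORT_DAY = 11
    PURCHASE = 12
    ESTRUS_PHASE = 13


def _label_to_int(label: str) -> int:
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def spawn_rng(seed: int, stream_label: str) -> np.random.Generator:
    """Return an independent, reproducible Generator for (seed, label)."""
    ss = np.random.SeedSequence([int(seed), _label_to_int(stream_label)])
    return np.random.Generator(np.random.Philox(ss))


def _splitmix(x: np.ndarray) -> np.ndarray:
    # uint64 wraparound is the point here
    with np.errstate(over="ignore"):
        x = (x ^ (x >> _U64(30))) * _MIX1
        x = (x ^ (x >> _U64(27))) * _MIX2
        return x ^ (x >> _U64(31))


class CounterRNG:
    """Stateless keyed generator over uint64 hashing (splitmix64 finalizer)."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        with np.errstate(over="ignore"):
            self._h0 = _splitmix(_U64(self.seed & 0xFFFFFFFFFFFFFFFF) + _GOLDEN)

    def _hash(self, *keys) -> np.ndarray:
        h = self._h0
        with np.errstate(over="ignore"):
            for k in keys:
                arr = np.asarray(k, dtype=np.int64).view(np.uint64)
                h = _splitmix((h ^ arr) + _GOLDEN)
        return h

    def uniform(self, *keys) -> np.ndarray:
        """Uniforms in the open interval (0, 1), one per broadcast key tuple."""
        h = self._hash(*keys)
        u = (h >> _U64(11)).astype(np.float64) * (2.0 ** -53)
        return np.clip(u, 2.0 ** -53, 1.0 - 2.0 ** -53)

    def normal(self, *keys) -> np.ndarray:
        """Standard normals via the inverse CDF of hashed uniforms."""
        return ndtri(self.uniform(*keys))

    def truncated_normal(self, *keys, lo: float = -3.0, hi: float = 3.0) -> np.ndarray:
        """Standard normal truncated to [lo, hi] via CDF inversion."""
        from scipy.special import ndtr

        a, b = ndtr(lo), ndtr(hi)
        u = self.uniform(*keys)
        return ndtri(a + u * (b - a))

    def bernoulli(self, p, *keys) -> np.ndarray:
        return self.uniform(*keys) < p
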