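"""Deterministic seed derivation helpers.

Every stochastic operation in the package takes an explicit integer seed.
Derived child seeds are produced with :class:`numpy.random.SeedSequence`
so that independent streams never collide, and are folded below 2**31 so
they remain valid seeds for any downstream RNG API.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "rng_from"]


def child_seed(seed: int, *key: int) -> int:
    """Derive a reproducible child seed (< 2**31) from ``seed`` and a key path."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(seed: int, *key: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from ``seed`` and a key path."""
    return np.random.default_rng(child_seed(seed, *key) if key else int(seed))
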