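"""Deterministic stream splitting on top of a counter-based generator.

Every stochastic operation in the package draws from a named substream of a
single base seed.  Streams are identified by a path of strings/integers, so
two breeding schemes sharing a base seed also share their founder and
burn-in gametes and diverge only where their mating plans differ.  Philox is
counter-based, which makes the split streams statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "as_rng"]


def stream(seed: int, *path: int | str) -> np.random.Generator:
    """Return the RNG substream identified by ``(seed, *path)``.

    String path components are hashed with CRC32 so stream identity does not
    depend on Python's randomized ``hash``.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for part in path:
        if isinstance(part, (int, np.integer)):
            keys.append(int(part) & 0xFFFFFFFF)
        else:
            keys.append(zlib.crc32(str(part).encode()))
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(keys)))


def as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    """Accept either a seed or an existing generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return stream(int(seed_or_rng))
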