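"""Named substream seeding.

One root seed drives a whole study; every stochastic stage draws from a
named substream so any single stage is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of stream names.

    The same (seed, names) pair always yields the same stream; distinct
    names yield statistically independent streams (SeedSequence mixing).
    """
    key = [int(seed) & 0xFFFFFFFFFFFFFFFF]
    key.extend(zlib.crc32(name.encode("utf-8")) for name in names)
    return np.random.default_rng(np.random.SeedSequence(key))
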