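"""Seed derivation shared across pipeline stages.

One global integer seed fans out deterministically to every stage via a
SeedSequence keyed on the stage name, so stages draw from disjoint
streams and adding a stage never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(seed: int, *tokens: str | int) -> int:
    """A child seed (< 2**31) for the stage identified by ``tokens``."""
    keys = [int(seed)]
    for t in tokens:
        keys.append(zlib.crc32(str(t).encode()) if isinstance(t, str) else int(t))
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def derive_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """A Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, *tokens))
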