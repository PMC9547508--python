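"""Named, independent random substreams derived from one global seed.

Every simulator entry point draws from ``substream(seed, name)`` so that a
single integer seed reproduces the whole pipeline while calls with different
names (or attempt counters) are statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str, attempt: int = 0) -> np.random.Generator:
    """Return a Generator for the (seed, name, attempt) substream.

    The stream key is derived from a CRC of ``name`` so the mapping is stable
    across sessions and platforms.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(int(seed), spawn_key=(key, int(attempt)))
    return np.random.default_rng(ss)
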