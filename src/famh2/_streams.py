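"""Named random-number substreams.

All randomness in the package flows from a single integer seed through
independently-seeded named substreams, so that adding a draw to one
component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for substream ``name`` of master ``seed``.

    The substream key is derived from a CRC32 of the name so that streams
    are stable across sessions and independent of call order.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
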