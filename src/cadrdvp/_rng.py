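"""Named, independent random streams derived from one integer seed.

Each generator in the package draws from its own named stream so that adding
a new stage never shifts the randomness consumed by existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of master ``seed``.

    The substream key is a CRC32 of the name, so streams are stable across
    sessions and independent for distinct names.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
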