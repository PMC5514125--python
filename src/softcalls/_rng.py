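"""Deterministic RNG stream splitting.

Every stochastic operation in the package draws from its own
:class:`numpy.random.Generator`, derived from a single base seed plus a
tuple of string/integer tags naming the operation (e.g. ``("synth",
"waveform", bird_id)``).  String tags are hashed with CRC-32 so the
spawn key is stable across sessions and platforms.  Regenerating one
stage therefore never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng"]


def _key(tag: int | str) -> int:
    if isinstance(tag, (int, np.integer)):
        if tag < 0:
            raise ValueError("integer rng tags must be non-negative")
        return int(tag)
    return zlib.crc32(str(tag).encode("utf-8"))


def split_rng(seed: int, *tags: int | str) -> np.random.Generator:
    """Return an independent generator for ``(seed, *tags)``.

    Identical arguments always yield an identical stream; distinct tag
    tuples yield streams that are independent by construction
    (:class:`numpy.random.SeedSequence` spawn keys).
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key(t) for t in tags))
    return np.random.default_rng(ss)
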