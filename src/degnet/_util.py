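"""Seeded RNG substreams shared across the package.

A single integer seed fans out into named, order-independent substreams so
that any stage of the pipeline can be re-run standalone and reproduce the
exact draws it made inside a full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(part: int | str) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    return int(part) & 0xFFFFFFFF


def substream(seed: int, *parts: int | str) -> np.random.Generator:
    """Return a Generator for the substream named by ``parts`` under ``seed``.

    The same (seed, parts) always yields the same stream; distinct parts
    yield statistically independent streams (SeedSequence spawning keys).
    """
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=tuple(_key(p) for p in parts))
    return np.random.default_rng(ss)
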