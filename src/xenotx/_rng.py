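"""Named random streams derived from one master seed.

Every stochastic stage of the pipeline draws from its own child stream so
that regenerating one stage (counts, signatures, graph, permutations) does
not perturb the others.  Streams are derived with ``numpy.random.SeedSequence``
spawn keys obtained by hashing the stream name, which is stable across
processes and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across Python processes (unlike hash()).
    return zlib.crc32(name.encode("utf-8"))


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for stream *name* under master *seed*."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_name_key(name),)))


def stream_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(stream(seed, name).integers(0, 2**31 - 1))
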