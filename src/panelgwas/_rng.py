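"""Named deterministic RNG substreams.

One root seed drives the whole pipeline; each operation pulls its own
independent stream keyed by name, so modules can be re-run in isolation
without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream ``name`` derived from ``seed``.

    The (seed, name) pair fully determines the stream; distinct names give
    statistically independent streams via SeedSequence spawn keys.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
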