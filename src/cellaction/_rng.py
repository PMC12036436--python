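"""Deterministic named RNG substreams.

Every stochastic stage of a run draws from a substream derived from the
single master seed plus the stage name, so a stage can be re-run in
isolation and still reproduce the full-pipeline result.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for stage ``name`` derived from ``seed``.

    The stage name is hashed with CRC-32, which is stable across Python
    processes (unlike ``hash``), and combined with the master seed into a
    :class:`numpy.random.SeedSequence`.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
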