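"""Seed plumbing: one master seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of ``master_seed``.

    The stream is a pure function of (seed, name): the same pair always
    yields the same sequence, and distinct names give statistically
    independent streams (SeedSequence keying).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))
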