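"""Seeded random-number plumbing.

Every stochastic operation in the package takes an explicit integer seed and
derives an independent :class:`numpy.random.Generator` from it through
:func:`spawn`.  String tags let one user-facing seed fan out to statistically
independent streams (one per stage, replicate, channel, ...) without any
global state, and the derivation is stable across sessions and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["spawn"]


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    digest = hashlib.blake2s(str(tag).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def spawn(seed: int, *tags) -> np.random.Generator:
    """Derive a Generator from a base seed and a path of sub-stream tags."""
    entropy = [int(seed)] + [_tag_to_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
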