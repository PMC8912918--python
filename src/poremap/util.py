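"""Deterministic seed splitting.

All randomness in the package flows from one integer seed. Independent
streams for different purposes are derived by hashing a stable string label
into a :class:`numpy.random.SeedSequence` alongside the user seed, so adding
a new consumer never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *labels: str | int) -> np.random.Generator:
    """Child generator for ``seed`` scoped by one or more stream labels."""
    words = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            words.append(zlib.crc32(lab.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(lab) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
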