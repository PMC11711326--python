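"""Seed-stream helpers.

All randomness in the package flows from one base seed fanned out into named
streams, so independent stages (rendering, training, noise draws, metrics)
stay decoupled: changing how many draws one stage makes never shifts another
stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_seed(base_seed: int, *names: str) -> int:
    """Deterministic child seed (< 2**31) for a named stream."""
    tag = zlib.crc32("/".join(names).encode())
    mixed = np.random.SeedSequence([int(base_seed), tag]).generate_state(1)[0]
    return int(mixed % (2**31 - 1))


def stream_rng(base_seed: int, *names: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(base_seed, *names))
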