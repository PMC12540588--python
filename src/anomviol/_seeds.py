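"""Seed-stream plumbing.

A single master seed fans out into independent, reproducible substreams via
:class:`numpy.random.SeedSequence` spawn keys.  Each named stream has a fixed
counter so that adding a new stream never perturbs existing ones, and the same
(master seed, stream, index) triple always yields the same generator.
"""

from __future__ import annotations

import numpy as np

# Fixed counter per stream; append only, never reorder.
_STREAMS = {
    "temperature": 0,
    "rainfall": 1,
    "events": 2,
    "counts": 3,
    "incidents": 4,
    "replicates": 5,
}


def spawn_rng(master_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Return the generator for a named substream of ``master_seed``."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[stream], index))
    return np.random.default_rng(ss)


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` integer seeds (< 2**31) for independent replicates."""
    rng = spawn_rng(master_seed, "replicates")
    return rng.integers(0, 2**31 - 1, size=n)
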