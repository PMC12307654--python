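"""Deterministic random-number stream management.

One root seed per run; every generator draws from its own child stream derived
deterministically from the root via :class:`numpy.random.SeedSequence`, so adding
or reordering stages never perturbs the streams of the others.  The bit
generator is pinned to PCG64 for cross-platform reproducibility.
"""

from __future__ import annotations

import numpy as np

#: stable stream labels -> spawn key, so child streams are order-independent
_STREAMS = {
    "trajectories": 0,
    "frames": 1,
    "frap": 2,
    "tht": 3,
    "kinetics": 4,
    "condensate_image": 5,
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Return the PCG64 generator for a named stream under a root seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown RNG stream {stream!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    return np.random.Generator(np.random.PCG64(ss))
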