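"""Seed-stream management.

All randomness in the package flows from one root integer seed. Each named
consumer gets its own :class:`numpy.random.Generator` derived from the root
``SeedSequence`` by spawning with a fixed, documented key, so modules can be
exercised in isolation without perturbing each other's streams.
"""

from __future__ import annotations

import numpy as np

# Fixed spawn indices: changing this table changes every simulated cohort.
STREAMS = {
    "baseline": 0,
    "weather": 1,
    "latent": 2,
    "symptoms": 3,
    "physiology": 4,
    "events": 5,
    "missingness": 6,
    "folds": 7,
    "models": 8,
    "bootstrap": 9,
}


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for the named stream under the given root seed."""
    if name not in STREAMS:
        raise KeyError(f"unknown rng stream {name!r}; known: {sorted(STREAMS)}")
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(STREAMS))
    return np.random.default_rng(children[STREAMS[name]])


def substream(seed: int, name: str, index: int) -> np.random.Generator:
    """A reproducible child of a named stream (e.g. one per replicate)."""
    if name not in STREAMS:
        raise KeyError(f"unknown rng stream {name!r}; known: {sorted(STREAMS)}")
    root = np.random.SeedSequence(int(seed))
    child = root.spawn(len(STREAMS))[STREAMS[name]]
    return np.random.default_rng(child.spawn(int(index) + 1)[-1])
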