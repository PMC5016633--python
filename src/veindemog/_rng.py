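"""Seed-substream plumbing.

Each generator owns a fixed substream key so that adding a new generator (or
reordering calls) never perturbs the draws of another generator run under the
same root seed.
"""

from __future__ import annotations

import numpy as np

# Fixed, append-only substream ids. Never renumber.
SPECIES_PARAMS = 1
CENSUS = 2
TRAITS = 3
SOIL = 4
PHYLO = 5
BM_TRAIT = 6


def substream(seed: int, key: int) -> np.random.Generator:
    """Generator for substream ``key`` of root ``seed``."""
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a nonnegative integer, got {seed!r}")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(key),)))
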