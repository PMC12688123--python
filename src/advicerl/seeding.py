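"""Seed plumbing: one user-facing seed per run, hierarchically split into
stream-specific child seeds so each component is independently reproducible."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(rng_seed) -> np.random.SeedSequence:
    """Accept an int or an already-spawned SeedSequence."""
    if isinstance(rng_seed, np.random.SeedSequence):
        return rng_seed
    return np.random.SeedSequence(rng_seed)
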