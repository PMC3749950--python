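"""Deterministic random-number management.

Every stochastic routine takes a single integer root seed.  Child streams
(one per trajectory, per cell, per repetition) are derived with
``numpy.random.SeedSequence.spawn``, so ensembles are reproducible and the
result of trajectory *k* does not depend on how many other trajectories were
requested before it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["root_sequence", "spawn_rngs", "rng_from"]


def root_sequence(seed: int) -> np.random.SeedSequence:
    """Seed sequence for a root seed (plain integers only)."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.SeedSequence(int(seed))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """`n` independent generators derived from one root seed."""
    return [np.random.default_rng(s) for s in root_sequence(seed).spawn(n)]


def rng_from(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(root_sequence(seed_or_rng))
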