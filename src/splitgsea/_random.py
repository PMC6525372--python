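"""Seed handling: named, independent sub-streams from one top-level seed.

Split-statistic evaluation consumes two kinds of randomness (phenotype
permutations and cohort splits).  Deriving both from one user-facing seed
through independent ``SeedSequence`` children keeps observed statistics and
null distributions reproducible and mutually uncorrelated.
"""

from __future__ import annotations

import numpy as np

RandomState = "int | np.random.SeedSequence | np.random.Generator | None"


def as_seed_sequence(random_state) -> np.random.SeedSequence:
    """Coerce a user-supplied seed to a ``SeedSequence``.

    Generators are accepted by drawing a fresh entropy word from them, so a
    shared generator still yields distinct downstream streams per call.
    """
    if random_state is None:
        return np.random.SeedSequence()
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    if isinstance(random_state, np.random.Generator):
        return np.random.SeedSequence(int(random_state.integers(2**31)))
    return np.random.SeedSequence(int(random_state))


def as_generator(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(as_seed_sequence(random_state))


def substreams(random_state, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one seed, in a fixed order."""
    ss = as_seed_sequence(random_state)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
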