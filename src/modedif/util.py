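"""Seed handling shared by all stochastic stages.

Every stage accepts either a ``numpy.random.Generator`` or an integer seed.
A master seed is expanded into named child seeds via ``SeedSequence.spawn``
so that each stage (bank, persons, responses, DIF selection, CAT, MCMC
chains) draws from an independent stream and a run can be reproduced
bit-for-bit from the master seed alone.
"""

from __future__ import annotations

import numpy as np

RngLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from a master seed."""
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed.spawn(n)
    return np.random.SeedSequence(master_seed).spawn(n)


def spawn_rngs(master_seed, names: list[str]) -> dict[str, np.random.Generator]:
    """Named independent generators, one per pipeline stage."""
    children = spawn_seeds(master_seed, len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}
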