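"""Counter-based seed derivation.

All randomness in the package flows from a single master seed.  Child seeds
are derived from the master seed plus an integer path (e.g. ``(threshold_idx,
dataset_idx)``), so any single unit of work — one cohort, one forest, one
bootstrap — is reproducible in isolation without replaying everything that
came before it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]

#: Seeds handed to third-party libraries stay below 2**31.
_SEED_MOD = 2**31


def child_seed(master: int, *path: int) -> int:
    """Derive a deterministic child seed from ``master`` and an integer path.

    The derivation is a counter-based hash (``numpy.random.SeedSequence``
    with the path appended to the entropy), so distinct paths give
    statistically independent streams and the same path always gives the
    same seed.
    """
    entropy = [int(master) % _SEED_MOD] + [int(x) for x in path]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, np.uint32)[0]) % _SEED_MOD


def child_rng(master: int, *path: int) -> np.random.Generator:
    """A ``numpy`` Generator seeded with :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *path))
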