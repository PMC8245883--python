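"""Deterministic child-seed derivation for replicated simulations.

A study with master seed ``s`` gives replicate ``k`` the seed
``child_seed(s, k)``, derived through :class:`numpy.random.SeedSequence`
with entropy ``(s, k)``.  The rule is stable across platforms and numpy
versions, so replicate ``k`` can be re-simulated in isolation without
re-running replicates ``0 .. k-1``.
"""

from __future__ import annotations

import numpy as np


def child_seed(master_seed: int, index: int) -> int:
    """Seed for replicate ``index`` of a study with the given master seed."""
    if index < 0:
        raise ValueError("replicate index must be nonnegative")
    return int(np.random.SeedSequence((int(master_seed), int(index))).generate_state(1)[0])
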