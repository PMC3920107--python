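"""Deterministic seed derivation for batched simulations."""

from __future__ import annotations

import numpy as np


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from one master seed.

    Uses numpy's splittable SeedSequence so batches are order-independent:
    run ``k`` always receives the same seed for a given master, regardless of
    how many runs are requested or in what order they execute. Seeds are
    reduced below 2**31 so they fit any downstream integer-seeded RNG.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(int(n))]
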