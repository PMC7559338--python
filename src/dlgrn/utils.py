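"""Small shared helpers."""
from __future__ import annotations

import numpy as np


def as_rng(random_state) -> np.random.Generator:
    """Coerce an int / None / Generator into a numpy Generator."""
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Uses numpy's SeedSequence spawning so stage/run seeds are reproducible
    and statistically independent regardless of execution order.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
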