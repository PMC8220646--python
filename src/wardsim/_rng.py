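"""Named random sub-streams.

One master seed spawns independent, reproducible sub-streams keyed by a
stream code plus arbitrary integer coordinates (unit index, day, ...).
Scenarios that share a master seed therefore share demand, absence and
fulfilment randomness (common random numbers) regardless of which plan or
availability scenario is being simulated.
"""

from __future__ import annotations

import numpy as np

# Stream codes.  These are part of the reproducibility contract: changing
# them changes every simulated trajectory for a given master seed.
STRUCTURE = 0  # hospital/unit profile generation
DEMAND = 1  # simulation-period demand draws
ABSENCE = 2  # sickness absence slot draws
FILLS = 3  # bank/agency fulfilment draws
ESTABLISHMENT = 4  # 20-day establishment-setting sample


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the sub-stream addressed by ``key``.

    Deterministic given (master_seed, key); distinct keys give
    statistically independent streams.
    """
    seq = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(seq)


def keyed_uniforms(master_seed: int, *key: int, n: int) -> np.ndarray:
    """``n`` uniforms on [0, 1) addressed purely by ``key`` (counter-based).

    Uses the seed-sequence mixing hash directly, so the value at a given
    (key, position) never depends on how many draws other keys consumed.
    This is what couples bank/agency fulfilment draws across staffing plans
    and availability scenarios that share a master seed.
    """
    seq = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    words = seq.generate_state(n, dtype=np.uint64)
    return words / np.float64(2**64)
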