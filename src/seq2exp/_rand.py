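"""Seed derivation.

All randomness in the package flows from one master seed through
:func:`derive_rng`, which hashes the master seed together with a tuple of
integer keys (stage id, series id, repeat index, ...) via numpy's
``SeedSequence`` spawn-key mechanism.  Any sub-computation is therefore
reproducible in isolation given the master seed and its key path.
"""

from __future__ import annotations

import numpy as np

# stage keys, kept stable so that derived streams never collide across modules
STAGE_SEEDS = 0
STAGE_SERIES = 1
STAGE_PHENOTYPE = 2
STAGE_PARTITION = 3
STAGE_SAMPLING = 4
STAGE_MODEL = 5
STAGE_SCHEDULE = 6
STAGE_KMEANS = 7
STAGE_SEARCH = 8


def derive_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator deterministically derived from ``master_seed`` and ``keys``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return np.random.default_rng(ss)


def derive_int_seed(master_seed: int, *keys: int) -> int:
    """A plain integer seed below 2**31, for libraries that take ``random_state`` ints."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
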