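"""Shared fixtures: one small synthetic library and its partitions.

Session-scoped so that the library (the most expensive fixture) is generated
once and reused across test modules.
"""

from __future__ import annotations

import pytest

from seq2exp.experiment import PartitionSpec, make_partitions
from seq2exp.synthetic import LibraryConfig, build_library


@pytest.fixture(scope="session")
def small_library():
    """3 series x 700 variants of 30-nt regions; all five phenotype shapes cycle."""
    cfg = LibraryConfig(n_series=3, variants_per_series=700, length=30, master_seed=11)
    return build_library(config=cfg)


@pytest.fixture(scope="session")
def small_partitions(small_library):
    spec = PartitionSpec(train_pool_size=None, validation_per_series=70, seed=11)
    return make_partitions(small_library, spec)


@pytest.fixture(scope="session")
def shape_library():
    """5 series x 2000 variants at L=96: the scale at which shape contracts hold."""
    cfg = LibraryConfig(n_series=5, variants_per_series=2000, length=96, master_seed=1)
    return build_library(config=cfg)
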