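"""Shared fixtures: the reference simulation and its full pipeline run.

The expensive objects (24-array simulation, normalization, segmentation,
windowed testing) are session-scoped so every test file reuses one run.
"""

import warnings

import pytest

from plastotile import SimConfig
from plastotile.pipeline import (
    DEFAULT_SIM_SEED,
    run_pipeline,
    simulate_dataset,
)

warnings.filterwarnings("ignore", message="GC bins with <2 probes")


@pytest.fixture(scope="session")
def default_dataset():
    """The package's reference simulation (default config, pinned seed)."""
    return simulate_dataset(SimConfig(), seed=DEFAULT_SIM_SEED)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return run_pipeline(default_dataset)


@pytest.fixture(scope="session")
def null_dataset():
    """Same generator with no injected genotype effects (null comparison)."""
    cfg = SimConfig(de_effects=[], ncrna_de_effects=[], tss_shift_units=[])
    return simulate_dataset(cfg, seed=DEFAULT_SIM_SEED + 1000)


@pytest.fixture(scope="session")
def null_result(null_dataset):
    return run_pipeline(null_dataset)


@pytest.fixture()
def tiny_genome():
    from plastotile.io_formats import CircularGenome
    import numpy as np

    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    return CircularGenome("tiny", seq)
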