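import numpy as np
import pytest

from strandtile import run_simulate
from strandtile.synthetic_data import SimConfig


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A compact simulation: every architecture present, fast to segment."""
    kwargs = dict(
        seed=seed,
        genome_length=50_000,
        n_constitutive=4,
        n_meiotic_discrete=2,
        n_meiotic_utr3=2,
        n_fkh2_targets=2,
        n_new_antisense=2,
        n_internal_bidir=1,
        n_intron_spliced=1,
        n_intron_unspliced=1,
        n_twofold=1,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_run():
    """One full pipeline run on the compact simulation, shared across tests."""
    return run_simulate(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
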