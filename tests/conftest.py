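"""Shared fixtures: full-scale replication batches computed once per session."""

import numpy as np
import pytest

from adoloop.engine import run_study1_batch, run_study2_batch

BATCH_SEED = 1


@pytest.fixture(scope="session")
def study1_batch():
    """30 participants x {ado, random, fixed10}, 10 stages each."""
    return run_study1_batch(seed=BATCH_SEED)


@pytest.fixture(scope="session")
def study2_batch():
    """15 subjects per true model x {stable, volatile, ado}, 350 trials each."""
    return run_study2_batch(seed=BATCH_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
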