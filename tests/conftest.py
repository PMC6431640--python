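import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import somnoscore as sc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rodent_pair():
    """One-hour rodent-preset recording with ground-truth hypnogram."""
    return sc.generate_recording("rodent", 1.0, seed=11)


@pytest.fixture(scope="session")
def rodent_features(rodent_pair):
    rec, hyp = rodent_pair
    grid = sc.make_epoch_grid(rec, hyp.grid.epoch_length)
    return sc.extract_features(rec, grid, "ALL")


@pytest.fixture(scope="session")
def human_pair():
    """Four-hour human-preset recording (30 s epochs) with hypnogram."""
    return sc.generate_recording("human", 4, seed=12)


@pytest.fixture()
def animal_hypnogram():
    def make(tokens, epoch_length=4.0):
        labels = np.array(tokens, dtype=object)
        grid = sc.EpochGrid(epoch_length=epoch_length, n_epochs=len(labels))
        return sc.Hypnogram(grid=grid, vocabulary=sc.ANIMAL_VOCABULARY, labels=labels)

    return make


@pytest.fixture()
def human_hypnogram():
    def make(tokens, epoch_length=30.0):
        labels = np.array(tokens, dtype=object)
        grid = sc.EpochGrid(epoch_length=epoch_length, n_epochs=len(labels))
        return sc.Hypnogram(grid=grid, vocabulary=sc.HUMAN_VOCABULARY, labels=labels)

    return make
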