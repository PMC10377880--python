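import numpy as np
import pytest

from stfd import CohortSpec, SourceEpoch


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_epoch(rng):
    """5 sources x 40 samples at 10 Hz, random values."""
    return SourceEpoch(
        values=rng.normal(size=(5, 40)),
        coords=rng.normal(scale=50.0, size=(5, 3)),
        fs=10.0,
        subject_id="tiny",
        group="groupA",
    )


@pytest.fixture
def small_cohort_spec():
    """A cohort small enough for sub-second per-subject simulation."""
    return CohortSpec(
        n_groupA=3,
        n_groupB=3,
        n_sources=400,
        fs=50.0,
        epoch_seconds=5.0,
        seed=7,
    )
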