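import numpy as np
import pytest

from statefeats.synth import CohortConfig, generate_cohort

FS = 256.0


@pytest.fixture(scope="session")
def tone():
    """Unit-amplitude 10 Hz sine, 1 s at 256 Hz (on-bin pure tone)."""
    t = np.arange(int(FS)) / FS
    return np.sin(2 * np.pi * 10.0 * t)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 8 epochs/state x 2 units; shared by fold/classifier tests."""
    cfg = CohortConfig(n_subjects=3, n_epochs_per_state=8, n_spatial_units=2, master_seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_freqbands_table(small_cohort):
    from statefeats.classify import assemble_feature_table

    return assemble_feature_table(small_cohort, "FreqBands")
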