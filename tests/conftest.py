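import numpy as np
import pytest

import eegfatigue as ef


@pytest.fixture(scope="session")
def small_cohort_table():
    """Scaled FE+SE feature table from a small well-separated cohort."""
    cfg = ef.SynthConfig(
        n_subjects=3, n_channels=2, fs=128, minutes_per_state=0.25,
        effect_size=2.0, seed=42,
    )
    epochs = ef.assemble_dataset(ef.iter_cohort(cfg))
    table = ef.extract_features(epochs, "combined")
    return ef.scale_features(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
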