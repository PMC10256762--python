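import numpy as np
import pandas as pd
import pytest

from taylorbp.preprocess import preprocess_subject
from taylorbp.simulate import SimConfig, generate_subject


def labels_frame(state):
    return pd.DataFrame({
        "beat_index": np.arange(state.n_beats),
        "onset_s": state.onset_s,
        "SBP": state.sbp,
        "DBP": state.dbp,
        "PP": state.pp,
        "session": state.session,
    })


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free CPT+recovery subject (the segmentation/feature oracle)."""
    config = SimConfig(
        sessions=(("cpt", 120.0, 150.0), ("recovery", 120.0, 120.0)),
        noise_sd=0.0, seed=3,
    )
    trace, state = generate_subject(config)
    return config, trace, state


@pytest.fixture(scope="session")
def clean_dataset(clean_subject):
    config, trace, state = clean_subject
    return preprocess_subject(trace, labels_frame(state))


@pytest.fixture(scope="session")
def small_model_io():
    """Tiny random regression batch for network-level tests."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(12, 16))
    u = rng.normal(size=(12, 3))
    y = rng.normal(size=12)
    return x, u, y
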