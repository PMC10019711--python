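import numpy as np
import pytest

from tonemask import survival, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_records():
    """Four synthetic subjects on the Experiment-I grid."""
    cfg = synth.default_config("I", n_subjects=4, seed=11)
    return synth.generate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def small_survdata(small_records):
    df, _ = small_records
    cat = survival.categorize(df, "I")
    return survival.survival_data(survival.drop_first_block(cat))
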