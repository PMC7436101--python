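import numpy as np
import pytest

from apneapsg import SynthParams, generate_record
from apneapsg.pipeline import extract_features


@pytest.fixture(scope="session")
def short_record():
    """A 10-minute synthetic record at nominal effect sizes."""
    return generate_record(SynthParams(n_patients=1, minutes_per_patient=10, seed=11), 0)


@pytest.fixture(scope="session")
def short_features(short_record):
    return extract_features(short_record)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
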