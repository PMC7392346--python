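import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_records():
    """Three clean labeled records used across modules."""
    from riboclass import SequenceRecord

    return [
        SequenceRecord("s1", "F1", "ACGUACGUAC"),
        SequenceRecord("s2", "F1", "GGGCCCAUAU"),
        SequenceRecord("s3", "F2", "UUUUAAAACG"),
    ]


@pytest.fixture
def separable_dataset(rng):
    """Two well-separated numeric classes for classifier-level checks."""
    a = rng.normal(loc=0.0, size=(30, 4))
    b = rng.normal(loc=8.0, size=(30, 4))
    X = np.vstack([a, b])
    y = np.array(["A"] * 30 + ["B"] * 30)
    return X, y
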