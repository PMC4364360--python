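import pytest
from hypothesis import HealthCheck, settings

from roughnet.datasets import load_heart_sample

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def heart_sample():
    """The bundled six-object, three-attribute heart-disease table."""
    return load_heart_sample()
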