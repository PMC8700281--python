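import pytest
from hypothesis import settings

from ctdna_screen import DetectionCriterion, DrawSpec, ShedModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def model():
    return ShedModel()


@pytest.fixture
def draw():
    return DrawSpec()


@pytest.fixture
def criterion():
    return DetectionCriterion()
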