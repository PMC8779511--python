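import pytest

from thermocomfort.core import PipelineConfig
from thermocomfort.metabolic import fit_activity_classifier
from thermocomfort.synthetic import generate_activity_dataset


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_classifier():
    """A random-forest activity classifier trained on a small synthetic set."""
    return fit_activity_classifier(generate_activity_dataset(20, seed=11), seed=0)
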