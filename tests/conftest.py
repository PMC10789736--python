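import numpy as np
import pytest

from dermxai.ontology import default_ontology
from dermxai.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def ontology():
    return default_ontology()


@pytest.fixture(scope="session")
def small_bundle():
    """Cheap 48x48 dataset for fast unit tests."""
    cfg = GeneratorConfig(image_size=(48, 48), n_lesions=30, seed=5)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def study():
    """The desk-scale guided-vs-baseline comparison (trains two models)."""
    from dermxai.experiments import run_attention_study

    return run_attention_study(seed=123)


@pytest.fixture(scope="session")
def faithfulness_study(study):
    from dermxai.experiments import run_faithfulness_study

    return run_faithfulness_study(study, seed=123, n_images=100)
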