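import numpy as np
import pytest

from pronocase import annotation, synthetic_data


@pytest.fixture(scope="session")
def template_annotator():
    return annotation.TemplateAnnotator()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small rendered synthetic dataset shared across tests."""
    out = tmp_path_factory.mktemp("ds") / "dataset"
    cfg = synthetic_data.GeneratorConfig(
        n_participants=12, tokens_min=1500, tokens_max=2500, seed=7
    )
    synthetic_data.generate_dataset(cfg, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
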