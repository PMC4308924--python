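import numpy as np
import pytest
from hypothesis import settings

from cardiobayes.io import packaged_burden_table
from cardiobayes.priors import build_prior_table
from cardiobayes.synthetic import GeneratorSpec, generate_from_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel_priors():
    """Prior odds computed from the packaged cardiac burden table."""
    return build_prior_table(packaged_burden_table())


@pytest.fixture(scope="session")
def synth_spec():
    return GeneratorSpec()


@pytest.fixture(scope="session")
def synth_priors(synth_spec):
    return synth_spec.make_prior_table()


@pytest.fixture(scope="session")
def small_corpus(synth_spec):
    """Seed-pinned synthetic corpus: 3 genes, 6 domains, ~160 variants."""
    return generate_from_model(synth_spec, 160, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
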