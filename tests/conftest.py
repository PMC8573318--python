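import numpy as np
import pytest

from epactive.geometry import build_synthetic_lead_field, make_fixture_geometry
from epactive.tissue import generate_corpus
from epactive.vae import VaeConfig, train_vae


@pytest.fixture(scope="session")
def geom200():
    """200-node fixture geometry shared by the property tests."""
    return make_fixture_geometry(n_nodes=200, seed=7)


@pytest.fixture(scope="session")
def geom300():
    return make_fixture_geometry(n_nodes=300, seed=11)


@pytest.fixture(scope="session")
def lead_field300(geom300):
    return build_synthetic_lead_field(geom300, n_leads=120, seed=11)


@pytest.fixture(scope="session")
def corpus300(geom300):
    """Full-size training corpus (10k fields) shared across the session."""
    return generate_corpus(geom300, n_fields=10_000, seed=21)


@pytest.fixture(scope="session")
def vae300(corpus300):
    """VAE trained at the study conditions (10k corpus, default protocol)."""
    return train_vae(corpus300, VaeConfig(seed=0))
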