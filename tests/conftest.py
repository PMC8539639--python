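import numpy as np
import pytest

from qeppi.descriptors import compute_properties_from_smiles
from qeppi.fixtures import (
    FixtureSpec,
    fixture_smiles_set,
    generate_property_vectors,
    synthetic_modeling_smiles,
)
from qeppi.scorer import build_model


@pytest.fixture(scope="session")
def fixture_set():
    """The packaged ~50-molecule SMILES collection."""
    return fixture_smiles_set()


@pytest.fixture(scope="session")
def modeling_smiles():
    """Combinatorial SMILES collection broad enough to fit a full model."""
    return synthetic_modeling_smiles(300, seed=0)


@pytest.fixture(scope="session")
def synthetic_populations():
    """Positive (PPI-like) and shifted negative property-vector populations."""
    spec = FixtureSpec(n_compounds=600, shift=0.6, seed=1)
    return (
        generate_property_vectors(spec, "positive"),
        generate_property_vectors(spec, "negative"),
    )


@pytest.fixture(scope="session")
def fitted_model(synthetic_populations):
    """A full scoring model fitted on the synthetic positive population."""
    pos, _ = synthetic_populations
    return build_model(pos, seed=1)


@pytest.fixture(scope="session")
def fixture_property_vectors(fixture_set):
    return [compute_properties_from_smiles(r.smiles) for r in fixture_set]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
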