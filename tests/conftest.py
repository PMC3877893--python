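"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest

from cyanoscreen.phylo import SubstitutionModel
from cyanoscreen.synthetic_data import SimulationSpec, emit_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """The default 12-taxon / 2-HGT synthetic screen, seed 1."""
    return emit_dataset(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def small_model():
    return SubstitutionModel()
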