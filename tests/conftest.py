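"""Shared fixtures for the pldtox test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pldtox.signatures import default_profile
from pldtox.synthetic_data import GeneratorConfig, make_dataset, make_family_sequence


@pytest.fixture(scope="session")
def profile():
    """The packaged (exemplar-compiled) reference profile."""
    return default_profile()


@pytest.fixture(scope="session")
def dataset0():
    """One deterministic fixture dataset shared across tests."""
    return make_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def family_record():
    """Factory for single synthetic family members with truth."""

    def make(clade: str, seed: int = 0, mutation_rate: float = 0.0, **kwargs):
        rng = np.random.default_rng(seed)
        return make_family_sequence(clade, rng, mutation_rate=mutation_rate, **kwargs)

    return make
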