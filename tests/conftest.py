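import numpy as np
import pytest

from conjointcheck import (
    MCMCConfig,
    draw_item_params,
    draw_person_params,
    simulate_responses,
)


@pytest.fixture(scope="session")
def rasch_data_1000x20():
    """A Rasch-generated dataset at the reference design (N=1000, J=20, narrow difficulty)."""
    persons = draw_person_params(1000, 0.0, 1.0, seed=101)
    items = draw_item_params(20, 0.0, 0.25, disc="rasch", seed=102)
    return simulate_responses(persons, items, seed=103), persons, items


@pytest.fixture(scope="session")
def small_rasch_data():
    """A small Rasch dataset for fast pipeline tests (N=300, J=12)."""
    persons = draw_person_params(300, 0.0, 1.0, seed=201)
    items = draw_item_params(12, 0.0, 0.49, disc="rasch", seed=202)
    return simulate_responses(persons, items, seed=203)


@pytest.fixture
def fast_cfg():
    """Minimal-length chain configuration for smoke tests."""
    return MCMCConfig(burn_in=100, kept_draws=200, seed=42)
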