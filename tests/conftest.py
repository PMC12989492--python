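"""Shared fixtures: the toy model and one simulated demo cohort."""

import pytest

from lentiflux.expression import counts_to_tpm
from lentiflux.flux_sim import simulate_cohort
from lentiflux.model_io import build_toy_model
from lentiflux.synthetic_data import generate_counts, make_demo_design


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def demo_design(toy_model):
    """Study conditions: 7 pairs, planted knockdowns/upregulation."""
    return make_demo_design(toy_model, seed=1)


@pytest.fixture(scope="session")
def demo_tpm(demo_design):
    return counts_to_tpm(generate_counts(demo_design))


@pytest.fixture(scope="session")
def demo_fluxes(toy_model, demo_tpm):
    return simulate_cohort(toy_model, demo_tpm.values)
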