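"""Shared fixtures: synthetic populations and spike datasets.

The 60-neuron dataset emulates the full experimental design (12
orientations x 8 variance levels x 2 drift directions x 15 trials) and is
expensive, so it is built once per session and shared across analysis,
clustering and decoding tests.
"""

import warnings

import numpy as np
import pytest

from vartune import synthetic, tuning

POP_SEED = 11
TRIAL_SEED = 12


@pytest.fixture(scope="session")
def population60():
    return synthetic.sample_population(60, seed=POP_SEED)


@pytest.fixture(scope="session")
def dataset60(population60):
    return synthetic.simulate_trials(population60, seed=TRIAL_SEED)


@pytest.fixture(scope="session")
def summaries60(dataset60):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summaries, table = tuning.summarize_population(dataset60)
    return summaries, table


@pytest.fixture(scope="session")
def truth60(population60):
    return {n.neuron_id: n for n in population60}


@pytest.fixture(scope="session")
def dataset_small():
    """8-neuron dataset for cheap end-to-end checks."""
    pop = synthetic.sample_population(8, seed=3)
    return synthetic.simulate_trials(pop, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
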