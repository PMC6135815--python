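from datetime import datetime, timedelta

import numpy as np
import pytest

from placebo_rct import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort with planted effects, shared across tests."""
    params = CohortParams(
        n_ptx=12,
        n_notx=6,
        responder_fraction_ptx=0.5,
        n_nodes=24,
        n_timepoints=80,
        planted_edges=[(2, 7, 0.4, True), (3, 11, 0.4, False)],
        planted_subscale_effects=[(0, 0.7), (5, 0.6)],
        seed=42,
    )
    return generate_cohort(params)


@pytest.fixture()
def visit_dates():
    start = datetime(2024, 1, 8, 8, 0)
    return [start + timedelta(days=d) for d in (0, 14, 28, 35, 49, 56)]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
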