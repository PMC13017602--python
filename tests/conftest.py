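import numpy as np
import pytest

import crc_screen_sim as cs


@pytest.fixture(scope="session")
def params():
    return cs.load_params()


@pytest.fixture(scope="session")
def small_world(params):
    """A 4000-person cohort with natural histories and the no-screening
    baseline run, shared across fast tests."""
    cohort = cs.generate_cohort(4000, params, seed=3)
    nh = cs.simulate_cohort_histories(cohort, params, seed=3)
    baseline = cs.run_strategy(cs.no_screening_spec(), cohort, nh, params, seed=3)
    return {"cohort": cohort, "nh": nh, "baseline": baseline, "seed": 3}


@pytest.fixture(scope="session")
def table2():
    return cs.load_table2()


@pytest.fixture(scope="session")
def fit_dists(params):
    return cs.calibrate_fit_distributions(params)
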