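import pytest

from preterm_cascade.cohort_cascade import run_cohort
from preterm_cascade.model_params import baseline_parameter_set
from preterm_cascade.scenario_engine import load_scenario_library


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameter_set()


@pytest.fixture(scope="session")
def library():
    return load_scenario_library()


@pytest.fixture(scope="session")
def baseline_by_table(baseline, library):
    """Current-care mortality restricted to each table's cause group."""
    out = {}
    for spec in library:
        if spec.boost_mode == "none":
            out[spec.table] = run_cohort(baseline, subconditions=spec.subcondition_filter)
    return out
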