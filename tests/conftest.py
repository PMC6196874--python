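import copy

import pytest

from pedometer_cea.markov_engine import MarkovParameters, load_default_params
from pedometer_cea.synthetic_data import SyntheticConfig, generate_trial


@pytest.fixture(scope="session")
def default_markov_params() -> MarkovParameters:
    return load_default_params()


@pytest.fixture()
def markov_params(default_markov_params) -> MarkovParameters:
    """A mutable copy of the shipped parameter set."""
    return copy.deepcopy(default_markov_params)


@pytest.fixture(scope="session")
def small_trial():
    """A small complete trial dataset shared across read-only tests."""
    cfg = SyntheticConfig(n_per_arm=120, seed=11)
    return generate_trial(cfg)


def toy_markov_params(**overrides) -> MarkovParameters:
    """Minimal hand-checkable parameter set (flat rates, short horizon)."""
    base = dict(
        cohort_size=1000.0,
        start_age=59,
        end_age=61,
        p_active_control=0.4,
        rr_active_by_arm={"control": 1.0, "postal": 1.5, "nurse": 1.2},
        rr_disease_given_active={"chd": 0.5, "stroke": 0.5, "t2d": 0.5},
        effect_duration_years=10,
        incidence_bands=[{"from_age": 0, "chd": 0.0, "stroke": 0.0, "t2d": 0.1}],
        mortality_bands=[{"from_age": 0, "all_cause": 0.02, "cvd_fraction": 0.5}],
        excess_mortality={"t2d": 0.05},
        state_costs={"t2d_annual": 1000.0},
        state_utilities={"event_free": 0.8, "t2d": 0.6},
        one_off_utility_gain=0.01,
        year1_cost_per_person={"control": 100.0, "postal": 80.0, "nurse": 150.0},
        intervention_cost_year1={"control": 0.0, "postal": 55.0, "nurse": 157.0},
        intervention_cost_year2={"control": 0.0, "postal": 5.0, "nurse": 4.0},
        participant_cost_per_person={"control": 20.0, "postal": 50.0, "nurse": 50.0},
        discount_rate_costs=0.0,
        discount_rate_qalys=0.0,
    )
    base.update(overrides)
    return MarkovParameters(**base)
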