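import numpy as np
import pandas as pd
import pytest

from antdol import (
    SimScenario,
    aggregate_events,
    pooled_scores,
    roster,
    score_records,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    """Events-only scale: one colony per treatment, short baseline."""
    return SimScenario(n_colonies_per_treatment=1, baseline_duration=120.0, seed=1234)


@pytest.fixture(scope="session")
def small_experiment(small_scenario):
    return simulate_experiment(small_scenario, include_trajectories=True)


@pytest.fixture(scope="session")
def small_records(small_experiment):
    """Per-trial and pooled score records for the small experiment."""
    ants = roster(small_experiment.design)
    agg = aggregate_events(small_experiment.events, ants, n_trials=3)
    return score_records(agg), pooled_scores(agg)


@pytest.fixture()
def rng():
    return np.random.default_rng(97531)
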