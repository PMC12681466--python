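import numpy as np
import pandas as pd
import pytest

from erfp import BehaviorParams, SwayParams, TrialEventsSpec, simulate_sway


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_behavior_params():
    """Four participants, one 40-trial block: fast but structurally complete."""
    return BehaviorParams.experiment1(
        n_participants=4, n_blocks=1, trials_per_cell=5
    )


@pytest.fixture
def sway_params():
    return SwayParams()


def make_trial_specs(n_trials=3, soa=100.0, rt=700.0, spacing=4500.0, load="n.a."):
    return [
        TrialEventsSpec(
            trial=i + 1, t0_ms=1000.0 + i * spacing, soa_ms=soa, rt_ms=rt, task_load=load
        )
        for i in range(n_trials)
    ]


@pytest.fixture
def small_recording():
    """Three-trial simulated recording used across IO/preprocess tests."""
    return simulate_sway(make_trial_specs(3), SwayParams(), seed=99)


@pytest.fixture
def trial_table():
    """Hand-built 2-participant, 1-block, 10-trial table (sorted)."""
    rows = []
    for p in (1, 2):
        for i in range(10):
            rows.append(
                {
                    "participant": p,
                    "block": 1,
                    "trial": i + 1,
                    "soa": 100 if i % 2 == 0 else 1000,
                    "task_load": "n.a.",
                    "tone": "low",
                    "orientation": "left",
                    "rt_ms": 600.0 + 5 * i,
                    "manual_error": False,
                    "vocal_error": False,
                }
            )
    return pd.DataFrame(rows)
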