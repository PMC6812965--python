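"""Shared fixtures: small seeded cohorts and synthetic epoch sets.

Everything is generated programmatically at test time; session-scoped
fixtures keep the expensive simulations shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import foxrabbit as fr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: Group-mean parameters of the standard rule-selection design.
EXP1_PARAMS = fr.ChoiceParams(ms=0.48, sm=-0.38, pe=0.21, ss=0.20)

RATES5 = [0.2, 0.35, 0.5, 0.65, 0.8]


def uniform_cohort(n_subjects, params, seed, **config_kwargs):
    """Cohort in which every subject shares the same generating parameters."""
    cfg = fr.SessionConfig(**config_kwargs)
    dist = lambda rng: params  # noqa: E731
    return fr.simulate_cohort(n_subjects, cfg, parameter_distribution=dist, rng=seed)


@pytest.fixture(scope="session")
def cohort12():
    """Default heterogeneous cohort: 12 subjects x 10 blocks x 80 trials."""
    trials, subjects = fr.simulate_cohort(12, rng=1)
    return trials, subjects


@pytest.fixture(scope="session")
def neural_cohort():
    """Eight subjects with three-opponent sessions and default synthetic epochs."""
    spec = fr.SignalSpec()
    cfg = fr.SessionConfig(opponent_rates=(0.25, 0.5, 0.75), n_blocks=6)
    rng = np.random.default_rng(7)
    sessions, epochs = {}, {}
    for i in range(8):
        sid = f"s{i:03d}"
        s = fr.simulate_session(cfg, rng)
        s["subject_id"] = sid
        sessions[sid] = s
        epochs[sid] = fr.simulate_neural_epochs(s, spec, rng)
    return sessions, epochs, spec


@pytest.fixture()
def toy_log():
    """Hand-built eight-trial log with known condition cell fractions.

    Outcomes [W L W W L L W L], switches [-, 1, 0, 1, 1, 0, 0, 1]:
    post-win trials {2,4,5,8} all switch (rate 1.0, n=4); post-loss trials
    {3,6,7} never switch (rate 0.0, n=3).
    """
    outcomes = ["win", "loss", "win", "win", "loss", "loss", "win", "loss"]
    switches = [np.nan, 1, 0, 1, 1, 0, 0, 1]
    return pd.DataFrame(
        {
            "subject_id": "s000",
            "block": 1,
            "trial_in_block": np.arange(1, 9),
            "opponent_rate": 0.5,
            "player_switch": switches,
            "opponent_switch": [np.nan] + [0] * 7,
            "outcome": outcomes,
            "action_error": 0,
            "rt_ms": 500.0,
            "role": "fox",
        }
    )
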