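"""Shared fixtures: one trained model bank and one full experiment run.

Training and the n=50/condition experiment are expensive relative to the
rest of the suite, so they are session-scoped and shared by the unit and
acceptance tests.
"""

import numpy as np
import pytest

from epigaze.config import RunConfig
from epigaze import experiment as xp


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def bank(cfg):
    return xp.train_default_bank(cfg)


@pytest.fixture(scope="session")
def results(cfg, bank):
    """Full 2x2 experiment at n=50/condition, uniform and biased priors."""
    uniform = xp.run_experiment(50, 42, cfg, bank)
    biased = xp.run_experiment(
        50, 42, cfg.replace(prior_mode="biased"), bank
    )
    return {"uniform": uniform, "biased": biased}


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    """Desk-scale config for CLI round trips."""
    return RunConfig(seed=5, n_actors=2, n_moves_per_actor=3, n_units=30)


def by_condition(result, name):
    return [r for r in result.records if r.condition == name]
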