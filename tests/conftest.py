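import numpy as np
import pytest

from placedyn.pipeline import analyze_session
from placedyn.synth import GeneratorConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 40-cell, 2-day synthetic experiment with the default noise level."""
    cfg = GeneratorConfig(n_cells=40, n_days=2, laps_per_session=40, seed=3)
    sessions, truth = generate_experiment(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def analyzed_day1(small_experiment):
    _, sessions, truth = small_experiment
    smap, pf, events = analyze_session(
        sessions[0], n_shuffles=200, rng=np.random.default_rng(11)
    )
    return smap, pf, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
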