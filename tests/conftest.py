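import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from posturemg.pipeline import PipelineConfig, analyze_trials
from posturemg.simulate import generate_dataset, small_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipe_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """12 trials in two conditions -- enough structure for metric tests."""
    cfg = small_config(n_subjects=2, n_reps=3,
                       conditions=(("floor", "open"), ("elevated", "closed")))
    trials, truths = generate_dataset(cfg, seed=11)
    return cfg, trials, truths


@pytest.fixture(scope="session")
def analyzed(small_dataset, pipe_config):
    """The small dataset pushed through preprocess/segment/metrics."""
    _, trials, truths = small_dataset
    processed, events, epochs, activity, indices, skipped = analyze_trials(
        trials, pipe_config)
    assert not skipped
    return {"processed": processed, "events": events, "epochs": epochs,
            "activity": activity, "indices": indices, "truths": truths}


@pytest.fixture(scope="session")
def tiny_grid():
    """16 trials covering the full 2x2 condition grid (for stats/pipeline)."""
    cfg = small_config(n_subjects=2, n_reps=2)
    trials, truths = generate_dataset(cfg, seed=5)
    return cfg, trials, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
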