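import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import topicimpute as ti

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def topic_sim():
    """Default 3-topic fixture with uniform 30% dropout on positive entries."""
    return ti.simulate(
        ti.SimulationConfig(seed=0, dropout_lambda_range=(0.3, 0.3), dropout_decay=None)
    )


@pytest.fixture(scope="session")
def pipeline_result(topic_sim):
    """One full pipeline run shared by imputation/transfer tests."""
    cfg = ti.PipelineConfig(n_topics=3, epochs=200, seed=0)
    return ti.impute_pipeline(topic_sim.observed_counts, cfg)


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(3)
    vals = rng.integers(0, 20, size=(5, 7)).astype(float)
    return ti.CountMatrix(
        vals, [f"c{i}" for i in range(5)], [f"g{j}" for j in range(7)]
    )
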