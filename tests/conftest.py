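import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heteropath import (
    ClassifierConfig,
    canonical_feature_paths,
    planted_benchmark,
    toy_network,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_net():
    """The fixed 3-lncRNA / 4-T / 2-protein benchmark network."""
    return toy_network()


@pytest.fixture(scope="session")
def feature_paths():
    return canonical_feature_paths()


@pytest.fixture(scope="session")
def benchmark():
    """Planted-signal network plus its 200 ground-truth-labeled pairs."""
    return planted_benchmark()


@pytest.fixture(scope="session")
def default_config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def benchmark_loocv(benchmark, feature_paths, default_config):
    """LOOCV scores and report on the planted benchmark (computed once)."""
    from heteropath import loocv

    network, labeled = benchmark
    scores, report = loocv(network, labeled, feature_paths, default_config)
    return labeled, scores, report


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
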