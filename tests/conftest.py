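import pytest
from hypothesis import HealthCheck, settings

import smallarea as sa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme():
    return sa.default_scheme()


@pytest.fixture(scope="session")
def all_models(scheme):
    return sa.enumerate_models(scheme)


@pytest.fixture(scope="session")
def strong_signal_synth():
    """Census-like synthetic population spanning the full area-size range."""
    spec = sa.PopulationSpec(n_areas=40, pop_size_range=(200, 78_457), seed=5)
    return sa.generate_population(spec)


@pytest.fixture(scope="session")
def strong_signal_table(strong_signal_synth, all_models):
    """Modeling table over all 2- and 3-member models: unbalanced, strong signal."""
    models = [m for m in all_models if m.size <= 3]
    return sa.build_modeling_table(strong_signal_synth, models)
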