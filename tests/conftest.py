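import pytest

from efwsens import generate_study, load_registry, load_reference_week38_chart


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def week38_chart():
    return load_reference_week38_chart()


@pytest.fixture(scope="session")
def small_study_charts():
    """Three synthetic datasets with overlapping but unequal week coverage."""
    return generate_study(n_datasets=3, master_seed=11)
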