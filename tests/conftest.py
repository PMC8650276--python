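import pytest

import chemsplit as cs


@pytest.fixture(scope="session")
def small_library():
    """4 series + 20 singletons + salt duplicates; shared across tests."""
    records, series = cs.generate_series_library(
        cs.SyntheticConfig(n_series=4, n_singletons=20, salt_duplicates_per_series=2, seed=101)
    )
    return records, series


@pytest.fixture(scope="session")
def small_activity(small_library):
    _, series = small_library
    return cs.generate_activity_table(
        series, cs.SyntheticActivityConfig(n_tasks=8, task_size_range=(10, 60), seed=7)
    )
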