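import warnings

import pytest

from dalksizer import ClinicalRangeWarning, generate_table, load_reference_table


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def default_grid():
    return generate_table()


@pytest.fixture
def ignore_range_warnings():
    """Silence the clinical-envelope warning for tests that probe the
    mathematical domain far outside it."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClinicalRangeWarning)
        yield
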