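import pytest

from moxpa.labeling import label_table
from moxpa.synthetic_data import default_fixture_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16 participants x 10 days (160 daily rows), seeded; spans all classes."""
    spec = default_fixture_spec(16, [10], seed=5)
    days, table = generate_cohort(spec)
    return days, table


@pytest.fixture(scope="session")
def labelled_small(small_cohort):
    _, table = small_cohort
    return label_table(table)


@pytest.fixture(scope="session")
def tiny_stream():
    """One participant, one day of minute records."""
    from moxpa.synthetic_data import generate_minute_stream

    spec = default_fixture_spec(1, [1], seed=2)
    return generate_minute_stream(spec.profiles[0], 1)
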