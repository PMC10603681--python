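import pytest
from hypothesis import settings

from broilerclim.comfort import load_tables
from broilerclim.scenario import fixture_path, load_fixture_config, read_trace

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def bench_cfg():
    """The packaged bench-test (14-day flock) controller configuration."""
    return load_fixture_config()


@pytest.fixture(scope="session")
def bench_frames():
    """The packaged bench-test sensor trace (30 s sample-and-hold)."""
    return read_trace(fixture_path("table5_trace.csv"))
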