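import pytest

from vitrace.benchmark import run_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """Shared mixed-fate benchmark at reduced scale (fast unit-level checks)."""
    return run_benchmark(seed=7, n_ancestors=120)
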