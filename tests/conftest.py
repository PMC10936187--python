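import pytest

from n2oflux import build_default_sweep, run_sweep


@pytest.fixture(scope="session")
def default_sweep():
    return build_default_sweep()


@pytest.fixture(scope="session")
def default_table(default_sweep):
    """Analytic-engine results for the full default sweep (computed once)."""
    return run_sweep(default_sweep, engine="analytic")
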