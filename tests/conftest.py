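import pytest

from famvar.simulate import default_spec, emit, simulate_cohort


@pytest.fixture(scope="session")
def sim():
    """The default synthetic cohort, seed 1 (shared across the suite)."""
    return simulate_cohort(default_spec(1))


@pytest.fixture(scope="session")
def sim_paths(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return emit(sim, out)
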