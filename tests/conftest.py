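import pytest

from mgc_cea import load_inputs, run_all_strategies


@pytest.fixture(scope="session")
def base_inputs():
    """The packaged base-case parameter set."""
    return load_inputs()


@pytest.fixture(scope="session")
def base_summaries(base_inputs):
    """Base-case outcomes for all three strategies."""
    return run_all_strategies(base_inputs)
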