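import pytest

from pgxcea import default_parameters, run_base_case


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_results(base_params):
    """Both strategies plus the incremental comparison at the base case."""
    return run_base_case(base_params)
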