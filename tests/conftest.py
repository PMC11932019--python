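import pytest

from strokecea import evaluate, load_parameters


@pytest.fixture(scope="session")
def params():
    """Base-case parameter set (published point values)."""
    return load_parameters()


@pytest.fixture(scope="session")
def base_result(params):
    """Base-case comparison, shared across tests."""
    return evaluate(params)
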