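import pytest

from strokecea.parameters import default_parameters
from strokecea.synthetic import degenerate_fixtures


@pytest.fixture(scope="session")
def ps():
    """Shipped default parameter set (session-wide, treated as immutable)."""
    return default_parameters()


@pytest.fixture(scope="session")
def fixtures():
    """Named degenerate parameter sets for engine identities."""
    return degenerate_fixtures()
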