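import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from acetotrace.simulate import (  # noqa: E402
    CommunitySimSpec,
    ToyGemSpec,
    generate_count_tables,
    generate_toy_gem,
)


@pytest.fixture(scope="session")
def linear_chain():
    return generate_toy_gem(ToyGemSpec("linear_chain"))


@pytest.fixture(scope="session")
def two_substrate():
    return generate_toy_gem(ToyGemSpec("two_substrate"))


@pytest.fixture(scope="session")
def cometabolism():
    return generate_toy_gem(ToyGemSpec("cometabolism"))


@pytest.fixture(scope="session")
def community():
    """Default planted-effect community tables (abundance, expression, metadata)."""
    return generate_count_tables(CommunitySimSpec(seed=7))
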