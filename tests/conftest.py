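import pytest

from netsets import SetManager, Tables, build_network


@pytest.fixture
def toy_network():
    """Five nodes on a path plus a chord; edge ids are deterministic."""
    return build_network(
        "toy",
        [
            ("n1", "pp", "n2"),
            ("n2", "pp", "n3"),
            ("n3", "pp", "n4"),
            ("n4", "pp", "n5"),
            ("n1", "pd", "n3"),
        ],
    )


@pytest.fixture
def toy_tables(toy_network):
    return Tables.for_network(toy_network)


@pytest.fixture
def toy_mgr(toy_network):
    return SetManager(toy_network)
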