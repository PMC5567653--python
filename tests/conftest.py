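import pytest

from csindel.fixtures import make_dgk_like_fixture


@pytest.fixture(scope="session")
def dgk():
    """The bundled DGK-like synthetic family at the default seed."""
    return make_dgk_like_fixture(42)


def build_alignment(rows, ids=None):
    """Small helper: Alignment from a list of row strings."""
    from csindel.alignment import Alignment
    if ids is None:
        ids = [f"s{i}" for i in range(1, len(rows) + 1)]
    return Alignment(ids=list(ids), rows=list(rows))


@pytest.fixture
def aln_factory():
    return build_alignment
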