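import pytest

from ontoetl import builtin_command_registry
from ontoetl.fixtures import make_gleason_fixture


@pytest.fixture(scope="session")
def registry():
    return builtin_command_registry()


@pytest.fixture
def gleason():
    """Fresh Gleason worked-example fixture (EAV layout, no documented total)."""
    fx = make_gleason_fixture()
    yield fx
    fx.connection.close()
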