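import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mesh():
    """Irregular five-triangle patch with interior hinges."""
    from dipid.mesh import ShellMesh
    r = np.random.default_rng(0)
    V = r.normal(size=(6, 3))
    tris = [(0, 1, 2), (2, 1, 3), (2, 3, 4), (0, 2, 4), (4, 5, 0)]
    return ShellMesh(V, tris)
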