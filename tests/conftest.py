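import numpy as np
import pytest

from phytovz.scenarios import base_params


@pytest.fixture(scope="session")
def pro():
    """Default *Prochlorococcus* parameter triple (no environment factors)."""
    return base_params("prochlorococcus")


@pytest.fixture(scope="session")
def pro_coex(pro):
    """A parameter point inside the oscillatory coexistence band."""
    return pro.with_(phiS=4.06e-10, tau=2.0)


@pytest.fixture(scope="session")
def pro_stable_interior(pro):
    """A quadratic-mortality parameter point with a stable interior state."""
    return pro.with_(phiS=3.0e-10, tau=0.37, dV2=70.0, dZ2=12.0)
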