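import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsadc import KineticParams, ReactionConditions

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def wt_params() -> KineticParams:
    """Wild-type-scale kinetics: Km 3.69 mM, kcat 4.25 /s, printed rate 1.1e-3 /s."""
    return KineticParams(Km=3.69, kcat=4.25, kinact=0.0011)


@pytest.fixture
def wt_cond() -> ReactionConditions:
    """Assay composition: 1.7 uM enzyme (25 ug/mL of a ~14.7 kDa monomer), 40 mM Asp."""
    return ReactionConditions(E0=1.7, S0=40.0)


@pytest.fixture
def wt_like_decay() -> KineticParams:
    """Parameters whose effective activity half-life at 40 mM substrate is 17.91 min."""
    lam_per_s = math.log(2) / (17.91 * 60.0)
    return KineticParams(Km=3.69, kcat=4.25, kinact=lam_per_s * (3.69 + 40.0) / 40.0)


@pytest.fixture
def minute_grid() -> np.ndarray:
    """Two half-lives of the wt-like variant, 13 samples."""
    return np.linspace(0.0, 36.0, 13)
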