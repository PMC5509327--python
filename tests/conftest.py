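import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def metafor_dataset():
    """Six heterogeneous studies with reference values from R metafor 4.8
    (rma method="DL" and ranktest with exact p), frozen as the independent
    oracle for the pooling and rank-correlation code paths."""
    return {
        "y": [0.05, 0.42, -0.30, 0.61, 0.10, -0.12],
        "se": [0.10, 0.12, 0.15, 0.09, 0.20, 0.11],
        "dl_estimate": 0.134640616540,
        "dl_se": 0.148691458653,
        "tau2": 0.115619658656,
        "Q": 46.187950532646,
        "i2": 89.174665811452,
        "h2_classical": 9.237590106529,
        "ci": (-0.156789287228, 0.426070520308),
        "p": 0.365198776632,
        "fe_estimate": 0.199385511367,
        "fe_se": 0.047405062600,
        "begg_tau": -1.0 / 3.0,
        "begg_exact_p": 0.469444444444,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
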