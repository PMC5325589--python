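import numpy as np
import pytest

from lysoquant import pipelines


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def emission_calibration():
    """Linear emission calibration built once from noiseless clamp standards
    (pH 4.0, 4.5, 5.0, 5.5) through the full fit pipeline."""
    return pipelines.build_emission_calibration()
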