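import numpy as np
import pytest

from cardioquant import AnalysisConfig, PhantomSpec, generate_phantom


def make_disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def standard_phantom():
    """Default-condition phantom with all three channels and ground truth."""
    return generate_phantom(PhantomSpec(seed=21, n_perivascular=8))


@pytest.fixture(scope="session")
def standard_row(standard_phantom):
    """Full-pipeline feature row for the standard phantom (expensive)."""
    from cardioquant import analyze_image

    img, _ = standard_phantom
    return analyze_image(img, AnalysisConfig(), image_id="standard")
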