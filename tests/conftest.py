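import numpy as np
import pytest

from lopdwi import phantom, sampling


@pytest.fixture(scope="session")
def spiral_full():
    """164-point antipodally symmetric exact spiral (auto turns)."""
    return sampling.generate_exact_spiral(164, turns="auto")


@pytest.fixture(scope="session")
def spiral_hemi(spiral_full):
    """82-direction hemisphere reduction of the exact spiral."""
    return sampling.to_hemisphere(spiral_full)


@pytest.fixture(scope="session")
def electrostatic_82():
    """82-direction electrostatic scheme (expensive; shared)."""
    return sampling.generate_electrostatic(82, seed=1)


@pytest.fixture(scope="session")
def test_phantom():
    """Ground truth of the default desk-scale phantom."""
    return phantom.build_ground_truth(phantom.default_test_spec(), seed=0)


@pytest.fixture(scope="session")
def clean_b1000(test_phantom, spiral_hemi):
    """Noise-free phantom signal at b = 1000 s/mm^2."""
    return phantom.simulate_signal(test_phantom, spiral_hemi.with_bvalue(1000.0))


@pytest.fixture(scope="session")
def clean_b3000(test_phantom, spiral_hemi):
    return phantom.simulate_signal(test_phantom, spiral_hemi.with_bvalue(3000.0))


def axis_angle_deg(a, b):
    """Angle between two axes (antipodally symmetric), degrees."""
    return float(np.degrees(np.arccos(np.clip(abs(float(np.dot(a, b))), 0.0, 1.0))))
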