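import math

import numpy as np
import pytest

from pocketframe.synthetic_structures import BundleSpec, make_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """Default 7-helix synthetic bundle with its annotations and ground truth."""
    return make_bundle(BundleSpec())


@pytest.fixture(scope="session")
def triangle_bundle():
    """Minimal 3-helix bundle (triangular lateral boundary)."""
    return make_bundle(BundleSpec(n_helices=3, toggle_helix=3, seed=1))


def outward_unit(helix_id: int, n_helices: int = 7) -> np.ndarray:
    """Radial unit vector of a helix position on the bundle circle."""
    theta = 2 * math.pi * (helix_id - 1) / n_helices
    return np.array([math.cos(theta), math.sin(theta), 0.0])
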