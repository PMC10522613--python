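import numpy as np
import pytest

from tribs import default_model
from tribs.synthetic import random_pose


@pytest.fixture(scope="session")
def model():
    """Default right-arm model with plausible adult segment lengths (mm)."""
    return default_model((150.0, 300.0, 260.0, 90.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def random_local_poses(model, rng):
    """Factory: n random non-degenerate poses as (commands, local points)."""

    def make(n=100):
        return [random_pose(rng, model) for _ in range(n)]

    return make


def marker_dict(local_points):
    """Measured-point dict -> marker-name dict for the extractors."""
    return {f"M{pid}": xyz for pid, xyz in local_points.items()}
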