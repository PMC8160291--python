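from __future__ import annotations

import numpy as np
import pytest

from radpipe import PhantomSpec, generate_phantom_pair


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small phantom for oracle tests: ~260 tumor voxels."""
    return PhantomSpec(
        grid_shape=(14, 14, 6), voxel_spacing=(1.0, 1.0, 2.0),
        tumor_radius=5.0, tumor_center=(6.5, 6.5, 2.5))


@pytest.fixture(scope="session")
def default_phantom():
    """One default-sized phantom pair with its truth mask."""
    pair, mask, latent = generate_phantom_pair(PhantomSpec(), class_label=1, seed=42)
    return pair, mask, latent


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
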