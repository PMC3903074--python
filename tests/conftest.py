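import numpy as np
import pytest

from embryoseg3d import PhantomParams, VoxelSpacing, generate_phantom

STUDY_SPACING = VoxelSpacing(0.09, 0.09, 0.71)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noise-free multi-nucleus phantom shared across tests."""
    params = PhantomParams(
        n_nuclei=5,
        n_frames=2,
        noise_sigma=0.0,
        spacing=STUDY_SPACING,
        frame_shape=(25, 260, 260),
        min_separation_factor=1.3,
        seed=42,
    )
    stack, truth = generate_phantom(params)
    return params, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
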