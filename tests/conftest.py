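import numpy as np
import pytest

from nvuq import io, synth


@pytest.fixture
def small_geometry():
    """Coarse-but-isotropic-enough grid for fast scene rendering."""
    return io.VoxelGeometry(pixel_size_xy=0.5, z_step=1.0)


@pytest.fixture
def fine_geometry():
    """Sampling fine enough to resolve diffraction-limited punctae."""
    return io.VoxelGeometry(pixel_size_xy=0.3, z_step=0.3)


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(42)
    data = rng.integers(0, 60000, size=(3, 5, 2, 32, 32)).astype(float)
    return io.HyperStack(data, io.VoxelGeometry(0.124, 2.5, 1.5),
                         ["tracer", "autofluorescence"], origin_depth=10.0)


@pytest.fixture
def nvc_movie():
    truth = synth.NvcTruth(d0_true=12.0, dilation_frac=0.2)
    movie, truth = synth.generate_nvc_timelapse(truth, noise_sd=0.0, seed=7)
    return movie, truth
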