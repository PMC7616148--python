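import numpy as np
import pytest

from mitoquant.image_quant import SegmentationConfig
from mitoquant.synthetic_data import SynthImageParams, generate_tissue_image


@pytest.fixture(scope="session")
def default_config() -> SegmentationConfig:
    return SegmentationConfig()


@pytest.fixture(scope="session")
def noiseless_params() -> SynthImageParams:
    """Small noiseless image with disjoint puncta: detection should be exact."""
    return SynthImageParams(
        image_size_px=(192, 192),
        pixel_size_um=0.1,
        puncta_density_per_mm2=20000.0,
        poisson_noise=False,
        noise_sigma=0.0,
        puncta_min_gap_um=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_params):
    return generate_tissue_image(noiseless_params)


def make_grid(rng: np.random.Generator, shape=(10, 10), levels=(100.0, 5000.0)) -> np.ndarray:
    """Random two-level grid used for hand-checkable detection inputs."""
    return rng.choice(np.asarray(levels), size=shape)
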