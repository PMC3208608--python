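from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurimetrics import GreyImage, PipelineConfig, generate_field, measure_field
from neurimetrics.synthetic import RenderParams

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: compact canvas for unit tests that do not need acquisition-scale fields
SMALL = RenderParams(shape=(320, 320))


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_field(cfg):
    """One acquisition-scale clean field plus its measurement, shared
    across tests that only read from it."""
    img, truth = generate_field(6, "clean", seed=3)
    seg, fm = measure_field(img, cfg)
    return img, truth, seg, fm


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_grey(rng: np.random.Generator, shape=(24, 24), bit_depth=8) -> GreyImage:
    hi = 2**bit_depth - 1
    return GreyImage(rng.integers(0, hi + 1, size=shape).astype(np.uint16), bit_depth=bit_depth)


def random_skeleton(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A one-pixel-wide skeleton obtained by thinning random blobs."""
    from scipy import ndimage as ndi
    from skimage import morphology as m

    blobs = ndi.gaussian_filter(rng.normal(size=shape), 3.0) > 0.12
    return m.skeletonize(blobs)
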