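import numpy as np
import pytest

import spinecyto as sc


@pytest.fixture(scope="session")
def default_tissue():
    """One default synthetic tissue image with its ground-truth period."""
    image, period = sc.gen_tissue_image(sc.TissueImageParams(seed=42))
    return image, period


@pytest.fixture()
def full_roi():
    def make(image: sc.ImageGrid) -> sc.RoiBox:
        return sc.RoiBox(0.0, image.dv_extent_um, width_um=image.ab_extent_um)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
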