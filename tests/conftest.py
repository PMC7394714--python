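import numpy as np
import pytest

from leafct.featgen import FeatureConfig
from leafct.phantom import PhantomSpec, generate, hand_label_sim
from leafct.preprocess import binarize_and_combine, local_thickness
from leafct.stack_io import ClassMap


@pytest.fixture(scope="session")
def tiny_spec():
    """Small but complete leaf phantom: all 7 classes, quick to render."""
    return PhantomSpec(
        shape=(24, 64, 64),
        epidermis_thickness=4,
        mesophyll_thickness=40,
        vein_count=2,
        vein_radius=4,
        sheath_thickness=2,
        void_radius_range=(2, 5),
        undulation_amplitude=(3, 2),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return generate(tiny_spec)


@pytest.fixture(scope="session")
def tiny_cfg():
    return FeatureConfig(gaussian_sigmas=(1, 2, 4), variance_windows=(3, 5))


@pytest.fixture(scope="session")
def tiny_lt(tiny_bundle):
    binary = binarize_and_combine(tiny_bundle.gridrec, tiny_bundle.phase, 80, 80)
    return local_thickness(binary, "cell")


@pytest.fixture(scope="session")
def tiny_labels(tiny_bundle):
    return hand_label_sim(tiny_bundle.truth, 8)


@pytest.fixture
def class_map():
    return ClassMap.default()


def random_blob_mask(rng, shape, p=0.5):
    """Random connected-ish binary volume for oracle comparisons."""
    from scipy import ndimage

    noise = rng.random(shape)
    smooth = ndimage.gaussian_filter(noise, 1.5)
    return smooth > np.quantile(smooth, 1 - p)
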