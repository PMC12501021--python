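import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_image():
    """One deterministic hairless synthetic lesion image plus its mask."""
    from dermofusion.synth import LesionSpec, generate_lesion_image

    return generate_lesion_image(LesionSpec(class_id=4), (96, 96), seed=11)


@pytest.fixture(scope="session")
def hairy_image():
    """A lesion image with drawn hair strokes and the exact stroke mask."""
    from dermofusion.synth import (HairSpec, LesionSpec, draw_hairs,
                                   generate_lesion_image)

    img, _ = generate_lesion_image(LesionSpec(class_id=5, noise_sigma=3.0),
                                   (96, 96), seed=21)
    return draw_hairs(img, HairSpec(n_strokes=3, thickness=2), seed=22)
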