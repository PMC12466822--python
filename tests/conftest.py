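import numpy as np
import pytest

from sowestrus.scenegen import ESTRUS, NON_ESTRUS, render_scene, sample_spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scenes():
    """Blur-free, occlusion-free rendered scenes with ground truth."""
    rng = np.random.default_rng(777)
    scenes = []
    for i in range(40):
        label = ESTRUS if i % 2 == 0 else NON_ESTRUS
        spec = sample_spec(
            label,
            rng,
            image_size=(96, 96),
            sow_id=f"sow_{i % 8:03d}",
            blur_choices=(0.0,),
            bar_choices=(0,),
        )
        img, truth = render_scene(spec, rng)
        scenes.append((spec, img, truth))
    return scenes
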