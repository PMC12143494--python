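import numpy as np
import pytest

import retina_em as r


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    return r.ModelConfig.tiny(n_classes=3, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return r.build_model(tiny_config)


@pytest.fixture(scope="session")
def small_corpus():
    spec = r.SyntheticSpec(image_size=64, seed=3)
    return r.generate_pretrain_corpus(8, spec)


@pytest.fixture(scope="session")
def labeled_image():
    """One 64x64 synthetic image with a 2-foreground-class label map."""
    spec = r.SyntheticSpec(image_size=64, volume_shape=(1, 64, 64),
                           n_classes=2, objects_per_class=(2, 3), seed=5)
    vol, lab = r.generate_labeled_volume(spec)
    return vol[0], lab.data[0].astype(np.int64)
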