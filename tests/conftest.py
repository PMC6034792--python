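import numpy as np
import pytest

import octaquant as oq


@pytest.fixture(scope="session")
def default_spec():
    return oq.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return oq.generate_phantom(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    # smaller grid keeps feature/training tests fast
    return oq.PhantomSpec(size_px=160, avascular_radius_um=400.0, n_vessel_seeds=18, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return oq.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    image, _ = small_phantom
    return oq.compute_features(image)


@pytest.fixture(scope="session")
def config():
    return oq.PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def small_model(small_stack, small_phantom, config):
    _, truth = small_phantom
    aset = oq.sample_annotations(truth, seed=5)
    return oq.train(small_stack, aset, config)
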