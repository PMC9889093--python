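import numpy as np
import pytest

import clearquant as cq

# Small lateral size keeps a full simulate->segment->quantify cycle around
# 0.1 s while retaining the full 500 µm depth range the method targets.
SMALL_SHAPE = (32, 32, 100)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene():
    return cq.make_scene(cq.SceneParams(shape=SMALL_SHAPE, seed=7))


@pytest.fixture
def noise_free():
    return cq.NoiseParams(background_level=0.0, gaussian_sd=0.0)


@pytest.fixture
def rendered_stack(small_scene):
    model = cq.AttenuationModel(kind="sigmoid", d_half_um=150.0)
    return cq.render_stack(small_scene, model, cq.NoiseParams(), seed=11)


def make_stack(voxels, spacing=5.0, **kw):
    return cq.ImageStack(voxels=np.asarray(voxels, dtype=float),
                         plane_spacing_um=spacing, **kw)
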