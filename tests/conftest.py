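import numpy as np
import pytest

from spvsim.fixtures import SceneObject, SceneSpec, make_scene


@pytest.fixture
def bottle_scene():
    """One centered bottle on the light tabletop background."""
    spec = SceneSpec(
        objects=(SceneObject("bottle", 64, 102, 128, 51),), size=(256, 256)
    )
    return make_scene(spec)


@pytest.fixture
def pair_scene():
    """Bottle and cup side by side (multiple-object setup)."""
    spec = SceneSpec(
        objects=(
            SceneObject("bottle", 64, 32, 128, 64),
            SceneObject("cup", 64, 160, 128, 64),
        ),
        size=(256, 256),
    )
    return make_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
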