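import numpy as np
import pytest

from lesionmetry.camera import default_camera
from lesionmetry.phantom2d import (
    PhantomSceneSpec,
    SupportSpec,
    centered_shape,
    render_phantom,
)


@pytest.fixture(scope="session")
def flat_scene():
    return PhantomSceneSpec(
        support=SupportSpec(kind="flat"),
        shape=centered_shape("ellipse", 14.137, aspect=0.8),
        texture_seed=1,
    )


@pytest.fixture(scope="session")
def flat_phantom(flat_scene):
    """Rendered flat phantom: (image, truth)."""
    return render_phantom(flat_scene, default_camera())


@pytest.fixture(scope="session")
def flat_detection(flat_phantom):
    from lesionmetry.ruler import detect_ruler

    image, _ = flat_phantom
    return detect_ruler(image)


@pytest.fixture()
def rng():
    """Fresh seeded generator per test, so tests stay order-independent."""
    return np.random.default_rng(12345)
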