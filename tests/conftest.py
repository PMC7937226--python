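import math
import warnings

import numpy as np
import pytest

from pelletmorph import SceneSpec, generate_scene

# scikit-image deprecation chatter is irrelevant to the behaviour under test
warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def default_scene():
    """One default-condition scene (30 pellets, gradient + noise), shared."""
    return generate_scene(SceneSpec(n_pellets=30, seed=1))


@pytest.fixture(scope="session")
def five_pellet_scene():
    """Five well-separated pellets of fixed radius 25 px."""
    return generate_scene(
        SceneSpec(
            n_pellets=5,
            seed=2,
            radius_mu_log=math.log(25.0),
            radius_sigma_log=1e-3,
            min_separation_px=120.0,
            image_shape=(480, 640),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
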