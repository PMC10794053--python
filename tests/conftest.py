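import numpy as np
import pytest

from shootcount import PointAnnotation, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_cfg():
    """One small crown, a handful of shoots: cheap but fully featured."""
    return SceneConfig(
        image_size=48,
        n_crowns=(1, 1),
        crown_radius=(12.0, 16.0),
        shoots_per_crown=(5, 9),
        cluster_spread=2.0,
        perspective_gain=2.0,
        blob_sigma=1.0,
        background_texture_scale=8.0,
        seed=7,
    )


@pytest.fixture
def random_points(rng):
    def make(n, width=40, height=40):
        pts = np.column_stack(
            [rng.uniform(0, width - 1e-6, n), rng.uniform(0, height - 1e-6, n)]
        )
        return PointAnnotation("rand", width, height, pts)

    return make
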