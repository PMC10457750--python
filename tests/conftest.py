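import numpy as np
import pytest

from treeheight.synthetic import (SceneSpec, default_intrinsics, make_tree,
                                  render_scene, suite_scene_specs)
from treeheight.types import CameraIntrinsics, DepthMap


@pytest.fixture(scope="session")
def small_intrinsics() -> CameraIntrinsics:
    return default_intrinsics(128)


@pytest.fixture(scope="session")
def small_scene(small_intrinsics):
    """One 128x128 rendered scene: (spec, rgb, truth depth, mask, heights)."""
    spec = SceneSpec(trees=[make_tree(8.0, 6.0)], intrinsics=small_intrinsics,
                     seed=11)
    rgb, truth, mask, heights = render_scene(spec)
    return spec, rgb, truth, mask, heights


@pytest.fixture(scope="session")
def two_tree_scene(small_intrinsics):
    spec = SceneSpec(trees=[make_tree(8.0, 6.0, x_m=-1.2),
                            make_tree(5.0, 4.5, x_m=1.4)],
                     intrinsics=small_intrinsics, seed=3)
    rgb, truth, mask, heights = render_scene(spec)
    return spec, rgb, truth, mask, heights


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_depth_pair(rng, shape=(20, 30), S=2.5, D=300.0, sigma=0.0,
                      valid_fraction=0.8):
    """Synthetic (relative, absolute) maps tied by A = S*R + D."""
    r = rng.uniform(0.0, 60.0, size=shape)
    valid = rng.random(shape) < valid_fraction
    a = S * r + D + (rng.normal(0, sigma, size=shape) if sigma else 0.0)
    a = np.clip(a, 1.0, 65535.0)
    relative = DepthMap(values=r, kind="relative", valid=valid)
    absolute = DepthMap(values=a, kind="absolute",
                        valid=np.ones(shape, dtype=bool))
    return relative, absolute
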