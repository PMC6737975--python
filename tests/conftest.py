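"""Shared fixtures: synthetic scenes at a few sizes, reused across modules.

Scene-building is the expensive part of the suite, so the standard scene and
its detections are session-scoped.
"""

import numpy as np
import pytest

from smfish3d import SceneParams, detect_spots, simulate_scene


@pytest.fixture(scope="session")
def standard_scene():
    """Default-parameter dual-channel scene (200 spots/channel, SNR 20)."""
    return simulate_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def standard_detections(standard_scene):
    a = detect_spots(standard_scene.stack_a)
    b = detect_spots(standard_scene.stack_b)
    return a, b


@pytest.fixture(scope="session")
def small_scene():
    """50 well-separated spots in a smaller volume; fast to detect."""
    params = SceneParams(
        shape=(12, 150, 150), n_spots=50, coloc_fraction=1.0, n_nuclei=0, seed=7
    )
    return simulate_scene(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
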