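import numpy as np
import pytest

import railphen as rp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rail():
    """The platform's stock rail setting: 344 cm/min at 15 frames/s."""
    return rp.RailConfig.from_speed("344 cm/min")


@pytest.fixture(scope="session")
def small_noiseless():
    """Tiny noise-free 2-stop strip with exact stop poses (shared oracle)."""
    cfg = rp.SceneConfig(n_stops=2, plants_per_stop=3, n_rows=1, seed=11,
                         range_noise=0.0, stop_perturb=(0.0, 0.0),
                         ground_roughness=0.0, ground_tilt_deg=0.0)
    scene = rp.generate_scene(cfg)
    streams, truth = rp.make_blocks(scene)
    return scene, streams, truth


@pytest.fixture(scope="session")
def small_noisy():
    """Tiny 2-stop strip under the study noise/perturbation conditions."""
    cfg = rp.SceneConfig(n_stops=2, plants_per_stop=3, n_rows=1, seed=5)
    scene = rp.generate_scene(cfg)
    streams, truth = rp.make_blocks(scene)
    return scene, streams, truth


def random_cloud(rng, n, with_intensity=True):
    xyz = rng.uniform(-5, 5, (n, 3))
    intensity = rng.uniform(0, 1, n) if with_intensity else None
    return rp.PointCloud(xyz, intensity)
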