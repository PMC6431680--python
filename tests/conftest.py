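import numpy as np
import pytest
from skimage import draw

from famet import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free rendering: no Gaussian noise, cytosol kept."""
    return SceneConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def scene_a_clean(clean_config):
    return generate_scene("A", clean_config, rng_seed=5)


@pytest.fixture(scope="session")
def scene_d_clean(clean_config):
    return generate_scene("D", clean_config, rng_seed=5)


@pytest.fixture(scope="session")
def truth_populations():
    """Ground-truth-only populations (50 scenes per class for A, B, D)."""
    cfg = SceneConfig(noise_sd=0.0)
    out = {}
    for label in ("A", "B", "D"):
        out[label] = [
            generate_scene(label, cfg, rng_seed=np.random.SeedSequence(11, spawn_key=(ord(label), i)))
            for i in range(50)
        ]
    return out


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    size = 2 * (radius + pad)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((size // 2, size // 2), radius)
    mask[rr, cc] = True
    return mask


def rect_mask(h: int, w: int, pad: int = 10) -> np.ndarray:
    mask = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    mask[pad : pad + h, pad : pad + w] = True
    return mask
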