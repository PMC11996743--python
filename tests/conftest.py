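import numpy as np
import pytest

from qdvision.colorimetry import mean_color_stats
from qdvision.imaging import RGBImage, detect_circle, extract_luminous_pixels
from qdvision.synth import AssayConfig, NoiseModel, SceneGeometry


@pytest.fixture
def small_assay():
    """Scaled-down biochip scene (64x64, r = 16) for simulation-heavy tests."""
    geom = SceneGeometry(image_shape=(64, 64), circle_center=(32.0, 32.0), circle_radius=16.0)
    return AssayConfig(geometry=geom, noise=NoiseModel(seed=0))


def measure_mean_stats(pixels, min_radius=8, max_radius=28):
    """Full measurement path: detect circle, extract all pixels, average colors."""
    img = RGBImage(pixels)
    region = detect_circle(img, min_radius, max_radius)
    sample = extract_luminous_pixels(img, region)
    return mean_color_stats(sample)


def seeded(*parts) -> int:
    """Stable sub-seed below 2**31 derived from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))
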