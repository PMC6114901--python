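import numpy as np
import pytest
import scipy.ndimage as ndi

from goitroscan import imaging, synth


def rolling_ball_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Independent rolling-ball reference: grayscale morphological opening
    with a ball-shaped (non-flat) structuring element, then subtraction."""
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = x**2 + y**2
    footprint = d2 <= r**2
    heights = np.where(footprint, np.sqrt(np.maximum(r**2 - d2, 0.0)) - r, 0.0)
    arr = np.asarray(image, dtype=np.float64)
    eroded = ndi.grey_erosion(arr, footprint=footprint, structure=heights)
    background = ndi.grey_dilation(eroded, footprint=footprint, structure=heights)
    return np.clip(arr - background, 0.0, None)


@pytest.fixture
def basic_spec():
    """A clean mid-size scene: gland on a mild gradient, light noise."""
    return synth.SceneSpec(
        image_size=(128, 128),
        gland_center=(64.0, 64.0),
        gland_axes=(16.0, 9.0),
        gland_peak_intensity=120.0,
        background_plane=(10.0, 0.05, 0.03),
        noise_sd=2.0,
        seed=42,
    )


@pytest.fixture
def centered_roi():
    return imaging.RegionOfInterest(32, 32, 64, 64)


def random_scene_spec(rng: np.random.Generator, **overrides) -> synth.SceneSpec:
    """Draw a random valid scene spec for oracle comparisons."""
    h = w = int(rng.integers(96, 140))
    ay = float(rng.uniform(8, 16))
    ax = float(rng.uniform(6, 12))
    kwargs = dict(
        image_size=(h, w),
        gland_center=(
            float(rng.uniform(ay + 2, h - ay - 3)),
            float(rng.uniform(ax + 2, w - ax - 3)),
        ),
        gland_axes=(ay, ax),
        gland_peak_intensity=float(rng.uniform(60, 180)),
        n_pigment_spots=int(rng.integers(0, 4)),
        background_plane=(
            float(rng.uniform(0, 25)),
            float(rng.uniform(-0.08, 0.08)),
            float(rng.uniform(-0.08, 0.08)),
        ),
        noise_sd=float(rng.uniform(0, 4)),
        seed=int(rng.integers(2**31)),
    )
    kwargs.update(overrides)
    return synth.SceneSpec(**kwargs)
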