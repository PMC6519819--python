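import numpy as np
import pytest

from estreamlab.dosemap import DoseMap


def gaussian_spot_map(
    n: int = 120,
    pixel_size: float = 1.36,
    center_px: tuple[float, float] = (60.0, 55.0),
    sigma_cm: float = 1.2,
    amplitude: float = 150.0,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> DoseMap:
    """Smooth single-hot-spot dose map resembling a panel stream spot."""
    rng = np.random.default_rng(seed)
    px_cm = pixel_size / 10.0
    rr, cc = np.mgrid[:n, :n]
    d2 = ((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2) * px_cm**2
    values = amplitude * np.exp(-d2 / (2 * sigma_cm**2))
    if noise_rms > 0:
        values = np.clip(values + rng.normal(0, noise_rms, values.shape), 0, None)
    return DoseMap(values, pixel_size, (0.0, 0.0), "gaussian-spot")


@pytest.fixture
def spot_map() -> DoseMap:
    return gaussian_spot_map()


@pytest.fixture
def noisy_spot_pair() -> tuple[DoseMap, DoseMap]:
    a = gaussian_spot_map(n=64, noise_rms=1.5, seed=3)
    b = gaussian_spot_map(n=64, noise_rms=1.5, seed=4, amplitude=147.0)
    return a, b
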