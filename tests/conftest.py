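import numpy as np
import pytest

from neurocult import CultureSpec, FieldImage, generate_timecourse


@pytest.fixture(scope="session")
def default_timecourse():
    """One 3-day default-spec culture shared across tests."""
    spec = CultureSpec(seed=1, n_days=3)
    images, truth = generate_timecourse(spec)
    return spec, images, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_and_curves_image():
    """Three bright discs plus two thin curves, with ground-truth masks."""
    shape = (128, 128)
    rr, cc = np.indices(shape)
    soma = np.zeros(shape, dtype=bool)
    img = np.full(shape, 20.0)
    for (r0, c0) in [(30, 30), (40, 95), (95, 60)]:
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= 49
        soma |= disc
        img[disc] = 1000.0
    neurite = np.zeros(shape, dtype=bool)
    for t in np.linspace(0, 1, 400):
        r = int(round(60 + 50 * t))
        c = int(round(10 + 100 * t + 15 * np.sin(3 * t)))
        if 0 <= r < 127 and 0 <= c < 127:
            neurite[r:r + 2, c:c + 2] = True
    for t in np.linspace(0, 1, 400):
        r = int(round(110 - 80 * t))
        c = int(round(20 + 40 * t))
        if 0 <= r < 127 and 0 <= c < 127:
            neurite[r:r + 2, c:c + 2] = True
    neurite &= ~soma
    img[neurite] = 600.0
    return FieldImage(pixels=img, bit_depth=32), soma, neurite
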