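import numpy as np
import pytest

from stereoloc import CircleFeature, FrameTemplate, PhantomSpec, make_phantom_slice


@pytest.fixture
def single_annulus_spec():
    """One ring marker at (30, 40), r=10, noiseless."""
    return PhantomSpec(width=96, height=96,
                       circles=[CircleFeature(30, 40, 10)], noise_sigma=0.0)


@pytest.fixture
def single_annulus(single_annulus_spec):
    img, truth = make_phantom_slice(single_annulus_spec)
    return img, truth


@pytest.fixture
def frame_template():
    """8-point planar template (mm); anchors A-B are the unique longest pair."""
    return FrameTemplate(
        points={
            "A": (0.0, 0.0), "B": (100.0, 0.0),
            "C": (15.0, 35.0), "D": (35.0, 20.0), "E": (50.0, 38.0),
            "F": (65.0, 15.0), "G": (80.0, 32.0), "H": (30.0, 5.0),
        },
        anchors=("A", "B"),
    )


def disc_phantom(seed: int, size: int = 128, sigma_max: float = 10.0):
    """One filled-disc marker with random sub-pixel center and radius.

    Shared by the recovery tests and the acceptance script: radius in
    [6, 20] px, Gaussian noise sigma uniform in [0, sigma_max] on the
    0-255 intensity scale.
    """
    rng = np.random.default_rng(seed)
    r = int(rng.integers(6, 21))
    a = rng.uniform(r + 4, size - 1 - r - 4)
    b = rng.uniform(r + 4, size - 1 - r - 4)
    sigma = rng.uniform(0.0, sigma_max)
    spec = PhantomSpec(width=size, height=size,
                       circles=[CircleFeature(a, b, r, filled=True)],
                       noise_sigma=sigma, seed=seed)
    img, truth = make_phantom_slice(spec)
    return img, (a, b, r)
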