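import numpy as np
import pytest

from echodenoise import GrayImage, PhantomSpec, make_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_image(rng):
    """Seeded 9x9 uniform image, the workhorse for oracle comparisons."""
    return GrayImage(rng.uniform(0.0, 1.0, (9, 9)))


def small_phantom_spec(size: int = 32, seed: int = 0) -> PhantomSpec:
    """Phantom geometry scaled down to a small square image."""
    return PhantomSpec(
        height=size,
        width=size,
        chamber_center=(size / 2, size / 2),
        chamber_radius=(size * 0.17, size * 0.22),
        ring_thickness=size * 0.08,
        seed=seed,
    )


@pytest.fixture()
def phantom32():
    return make_phantom(small_phantom_spec(32))
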