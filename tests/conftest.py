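import numpy as np
import pytest

from dgemric import AcquisitionProtocol, PhantomSpec


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Desk-scale phantom: 64x64 grid, ~600 disc pixels, noiseless."""
    return PhantomSpec(
        grid_size=64,
        ellipse_center=(36.0, 32.0),
        semi_axes=(18.0, 11.0),
        fat_region=(2, 8, 4, 60),
        noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture
def uniform_spec(small_spec) -> PhantomSpec:
    """Same geometry with a single T1 everywhere in the disc."""
    from dataclasses import replace

    return replace(
        small_spec,
        ring_t1_native=(1000.0,) * 5,
        ring_t1_post_contrast=(800.0,) * 5,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
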