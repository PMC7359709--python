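import pytest

from graftct.phantom import PhantomSpec, generate_phantom


def _make(mode: str, seed: int, **kw):
    spec = PhantomSpec(length=8.0, contrast_mode=mode, rng_seed=seed, **kw)
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def lumen_phantom():
    """Short radiopaque-lumen phantom (bright cast lumen, dark deposit)."""
    return _make("lumen_opaque", seed=11)


@pytest.fixture(scope="session")
def thrombus_phantom():
    """Short radiopaque-thrombus phantom (bright stained deposit)."""
    return _make("thrombus_opaque", seed=12)


@pytest.fixture(scope="session")
def four_material_phantom():
    """Short four-material phantom (dark lumen, deposit, wall, shrink ring)."""
    return _make("four_material", seed=13)


@pytest.fixture(scope="session")
def clean_lumen_phantom():
    """Thrombus-free radiopaque-lumen phantom (a clean cylinder)."""
    return _make("lumen_opaque", seed=14, thrombus_baseline=0.0, thrombus_amplitude=0.0)
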