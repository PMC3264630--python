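import pytest

from slidecache import build_pyramid, generate_slide


@pytest.fixture(scope="session")
def slide():
    """A 1024x768 synthetic H&E-like slide at 40x."""
    return generate_slide(1024, 768, 40.0, seed=11)


@pytest.fixture(scope="session")
def pyramid(slide):
    """Stored levels 40x / 10x / 1x, 256 px tiles."""
    return build_pyramid(slide, [40.0, 10.0, 1.0], tile_size=256)


@pytest.fixture(scope="session")
def tiny_slide():
    return generate_slide(128, 96, 40.0, seed=3)


@pytest.fixture(scope="session")
def tiny_pyramid(tiny_slide):
    return build_pyramid(tiny_slide, [40.0, 10.0], tile_size=32)
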