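import pytest

from fiberprobe import FiberSpec, ProbeConfig


@pytest.fixture
def na022():
    """Factory for the common NA = 0.22 fiber at a given core size (um)."""

    def make(core_size: float) -> FiberSpec:
        return FiberSpec(core_size=core_size, numerical_aperture=0.22)

    return make


@pytest.fixture
def multi_probe():
    """Default illumination/collection pair: r_c = 10 um, normal incidence."""
    return ProbeConfig(mode="multi", fiber_spacing=10.0)


@pytest.fixture
def single_probe():
    return ProbeConfig(mode="single")
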