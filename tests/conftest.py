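import numpy as np
import pytest

from vesselqpi.config import OpticalConfig, PhantomSpec


@pytest.fixture
def optical_config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=0)


def make_disc(shape, center, radius):
    """Disc mask: strictly interior pixels (x² + y² < r²)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 < radius**2


def make_annulus(shape, center, r_inner, r_outer):
    """Annulus mask: r_inner ≤ d < r_outer."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 >= r_inner**2) & (d2 < r_outer**2)


def make_broken_annulus(shape, center, r_inner, r_outer, arc):
    """Annulus with an angular arc removed (arc in radians, from +x axis)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    ann = make_annulus(shape, center, r_inner, r_outer)
    theta = np.arctan2(yy - center[0], xx - center[1])
    a0, a1 = arc
    return ann & ~((theta >= a0) & (theta <= a1))
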