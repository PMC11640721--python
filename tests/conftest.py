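import numpy as np
import pytest

from orbitmorph import PhantomSpec, VoxelGeometry, make_cohort, make_phantom


@pytest.fixture(scope="session")
def geometry():
    return VoxelGeometry(sx=0.5, sy=0.5, sz=3.0)


@pytest.fixture(scope="session")
def default_phantom():
    """A single noiseless default phantom with its analytic truth."""
    spec = PhantomSpec(noise_sd=0.0)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 10-subject cohort (20 orbits) for cross-module tests."""
    return make_cohort(10, seed=11)


def disk_mask(shape, center_rc, radius_px):
    """Digitized disk by pixel-center membership (independent of package code)."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px ** 2


def ellipse_mask(shape, center_rc, semi_r, semi_c, theta=0.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - center_rc[0], cc - center_rc[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / semi_c) ** 2 + (v / semi_r) ** 2 <= 1.0
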