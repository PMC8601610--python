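import numpy as np
import pytest

from hedgescape.landscape import (
    GRFConfig,
    LandscapeAllocation,
    Tessellation,
    allocate,
    build_tessellation_fixture,
)


@pytest.fixture(scope="session")
def tess188():
    """Paper-scale tessellation: 5.55 km extent, 188 polygons."""
    return build_tessellation_fixture(5.55, 188, seed=1)


@pytest.fixture(scope="session")
def tess60():
    """Mid-size tessellation used for season-long simulations."""
    return build_tessellation_fixture(5.55, 60, seed=0)


@pytest.fixture(scope="session")
def alloc60(tess60):
    return allocate(tess60, GRFConfig(phi=2.0, rho=0.5, p_crop=0.5,
                                      p_hedge=0.5, seed=3))


def manual_allocation(tess: Tessellation, crop: np.ndarray,
                      hedge: np.ndarray) -> LandscapeAllocation:
    """Hand-built allocation for deterministic dynamics scenarios."""
    crop = np.asarray(crop, dtype=bool)
    hedge = np.asarray(hedge, dtype=bool)
    return LandscapeAllocation(
        crop_label=crop,
        hedge_label=hedge,
        w_crop=crop.astype(float),
        w_hedge=hedge.astype(float),
        config=GRFConfig(),
    )


@pytest.fixture
def square1():
    """Unit square, one polygon, 4 boundary edges."""
    return build_tessellation_fixture(1.0, 1, seed=0)
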