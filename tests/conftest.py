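import numpy as np
import pytest

from ciliaflow import (
    BeadParams,
    CiliaParams,
    FluidParams,
    build_field,
    dimensionless_groups,
)


@pytest.fixture
def reference_cilia() -> CiliaParams:
    """Typical healthy-edge beating: 10 Hz, 8 um amplitude, 10 um wave, h=50 um."""
    return CiliaParams(a=8.0, beta=0.0, f=10.0, lam=10.0, phi_star=0.0, h=50.0)


@pytest.fixture
def water() -> FluidParams:
    return FluidParams(rho=1.0, mu=1.0)


@pytest.fixture
def polystyrene_bead() -> BeadParams:
    return BeadParams(R=2.25, rho_b=1.0)


@pytest.fixture
def reference_groups(reference_cilia, water, polystyrene_bead):
    return dimensionless_groups(reference_cilia, water, polystyrene_bead)


@pytest.fixture
def reference_field(reference_cilia, water, polystyrene_bead):
    return build_field(reference_cilia, water, polystyrene_bead)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
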