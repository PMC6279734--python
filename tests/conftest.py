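"""Shared fixtures: reference curve specs, small phantoms, RNG."""

import numpy as np
import pytest

from gatedpet.curves import ContinuousVolumeCurve
from gatedpet.phantom import CurveSpec, PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20180331)


@pytest.fixture(scope="session")
def cosine_curve():
    """V(t) = 300 + 100 cos(2 pi t / 0.2): the closed-form reference."""
    return ContinuousVolumeCurve(period=0.2, dc=300.0,
                                 harmonics=((100.0, 0.0),))


@pytest.fixture(scope="session")
def zl_hard_spec():
    """ZL-control group means without the (infeasible) 1/3MFR target."""
    return CurveSpec(edv=410.8, esv=155.1, heart_rate=331.0,
                     pfr=12.1, tpfr=35.4, n_harmonics=6)


@pytest.fixture(scope="session")
def zl_curve(zl_hard_spec):
    from gatedpet.phantom import synthesize_curve

    return synthesize_curve(zl_hard_spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, fast phantom configuration for pipeline tests."""
    return PhantomConfig(wall_thickness=2.0, psf_fwhm=0.8, voxel_size=1.0,
                         grid_shape=(26, 26, 26), total_counts=2.0e6,
                         supersample=2)


def random_feasible_spec(rng) -> CurveSpec:
    """Draw a curve spec comfortably inside the band-limited family."""
    edv = rng.uniform(300.0, 500.0)
    ef = rng.uniform(45.0, 70.0)
    hr = rng.uniform(250.0, 400.0)
    T = 60.0 / hr
    sv = edv * ef / 100.0
    t_fill = rng.uniform(0.45, 0.65) * T
    pfr = rng.uniform(2.2, 3.2) * sv / (t_fill * edv)
    tpfr = rng.uniform(0.25, 0.4) * t_fill * 1000.0
    return CurveSpec(edv=edv, esv=edv - sv, heart_rate=hr,
                     pfr=pfr, tpfr=tpfr)
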