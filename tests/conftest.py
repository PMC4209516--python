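import numpy as np
import pytest

from relaxovb.exchange import BloodInputCurve, r1b_from_crp
from relaxovb.mprage import MprageProtocol
from relaxovb.phantom import PhantomSpec


@pytest.fixture(scope="session")
def protocol():
    return MprageProtocol()


def make_blood_curve(times_min=(15.0, 30.0, 45.0, 55.0), c0=1.2,
                     half_life_min=96.0, r1b0=0.45):
    """Blood input curve following a monoexponential plasma decay."""
    t = np.asarray(times_min, dtype=float)
    base = BloodInputCurve(t * 60.0, np.full(t.size, r1b0 + 1.0), r1b0=r1b0)
    crp = c0 * 0.5 ** (t / half_life_min)
    return BloodInputCurve(t * 60.0, r1b_from_crp(crp, base), r1b0=r1b0)


@pytest.fixture(scope="session")
def blood_curve():
    return make_blood_curve()


def small_spec(seed=0, snr=100.0, **kw):
    """Down-scaled phantom for unit tests (same structure, ~10x fewer voxels)."""
    defaults = dict(
        shape=(48, 48, 24),
        brain_semiaxes_mm=(22.0, 22.0, 20.0),
        ventricle_semiaxes_mm=(3.0, 8.0, 5.0),
        ventricle_offset_mm=5.0,
        n_dwmh=2,
        dwmh_radius_mm=2.5,
        dwmh_clearance_mm=6.0,
        sinus_z_mm=38.0,
        sinus_radius_mm=2.0,
        snr=snr,
        seed=seed,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """One small noisy study shared by read-only tests."""
    from relaxovb.phantom import generate_study

    spec = small_spec(seed=11)
    datasets, truth = generate_study(spec, (-20.0, 15.0, 30.0, 45.0, 55.0))
    return spec, datasets, truth


@pytest.fixture(scope="session")
def small_noiseless_study():
    from relaxovb.phantom import generate_study

    spec = small_spec(seed=11, snr=None)
    datasets, truth = generate_study(spec, (-20.0, 15.0, 30.0, 45.0, 55.0))
    return spec, datasets, truth
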