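import numpy as np
import pytest
from hypothesis import settings

from hbsquant import simdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hbsquant.planar import ROISet


@pytest.fixture(scope="session")
def params() -> simdata.KineticParams:
    return simdata.KineticParams()


@pytest.fixture(scope="session")
def planar_phantom() -> simdata.PhantomSpec:
    return simdata.make_planar_phantom(matrix=64, flr_fraction=0.3)


@pytest.fixture(scope="session")
def spect_phantom() -> simdata.PhantomSpec:
    return simdata.make_spect_phantom(shape=(32, 40, 40), flr_fraction=0.3)


@pytest.fixture(scope="session")
def acq_noise_free() -> simdata.AcquisitionSpec:
    return simdata.AcquisitionSpec(matrix=64, noise=False, seed=7)


@pytest.fixture(scope="session")
def noise_free_study(planar_phantom, params, acq_noise_free):
    """Noise-free anterior/posterior stacks plus anterior-orientation ROIs."""
    ant, post = simdata.render_dynamic(planar_phantom, params, acq_noise_free)
    rois = ROISet(liver=planar_phantom.liver_mask, bloodpool=planar_phantom.bloodpool_mask)
    return ant, post, rois


@pytest.fixture(scope="session")
def analytic_curves(params, acq_noise_free):
    t = acq_noise_free.frame_mid_times
    return simdata.solve_kinetics(params, t)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
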