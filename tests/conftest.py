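import numpy as np
import pytest

from sim3d.data_model import AcquisitionGeometry, Layout
from sim3d.otf import compute_psf, psf_to_otf
from sim3d.separation import separate_bands
from sim3d.simulator import SimConfig, make_phantom, simulate_raw_stack

SIM_SHAPE = (8, 128, 128)
SIM_SEED = 3


@pytest.fixture(scope="session")
def omx_geometry():
    return AcquisitionGeometry(layout=Layout.OMX)


@pytest.fixture(scope="session")
def world500():
    """Filament network imaged at 500 peak photons (moderate SNR)."""
    cfg = SimConfig(seed=SIM_SEED, peak_photons=500.0)
    gt = make_phantom("filaments", SIM_SHAPE, seed=SIM_SEED)
    stack, truth = simulate_raw_stack(gt, cfg)
    return stack, truth, gt


@pytest.fixture(scope="session")
def world_noiseless():
    cfg = SimConfig(seed=SIM_SEED, peak_photons=None)
    gt = make_phantom("filaments", SIM_SHAPE, seed=SIM_SEED)
    stack, truth = simulate_raw_stack(gt, cfg)
    return stack, truth, gt


def _separate_all(stack):
    geom = stack.geometry
    phases = 2 * np.pi * np.arange(geom.n_phases) / geom.n_phases
    return [
        separate_bands(stack.data[a].astype(np.float64), phases,
                       geometry=geom, angle_index=a)
        for a in range(geom.n_angles)
    ]


@pytest.fixture(scope="session")
def bands_noiseless(world_noiseless):
    stack, truth, _ = world_noiseless
    return _separate_all(stack), truth


@pytest.fixture(scope="session")
def otf_default(world_noiseless):
    stack, _, _ = world_noiseless
    psf = compute_psf(stack.geometry, SIM_SHAPE)
    return psf_to_otf(psf, stack.geometry)


@pytest.fixture(scope="session")
def separate_all():
    return _separate_all
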