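import numpy as np
import pytest

from zflex.basis import BasisSpec
from zflex.field import molecular_mask, _unit_coords
from zflex.synthdata import bending_mode, default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def spec():
    return BasisSpec(3, 2)


@pytest.fixture(scope="session")
def scene48():
    """Default 48^3 test scene: phantom, pseudo-atomic model."""
    return make_phantom(default_phantom_spec(box=48, voxel_size=2.0))


@pytest.fixture(scope="session")
def scene32():
    return make_phantom(default_phantom_spec(box=32, voxel_size=2.0))


@pytest.fixture(scope="session")
def mode48(spec, scene48):
    phantom, _ = scene48
    return bending_mode(spec, phantom.default_scale_radius)


@pytest.fixture(scope="session")
def mask_points48(scene48):
    """Unit-ball coordinates of the molecular-mask voxels of the 48 scene."""
    phantom, _ = scene48
    mask = molecular_mask(phantom)
    u = _unit_coords(phantom.box, phantom.voxel_size,
                     phantom.default_scale_radius)
    sel = (mask.values.reshape(-1) > 0) & (np.linalg.norm(u, axis=1) <= 1.0)
    return u[sel]


def field_rel_rmse(c_est, c_true, pts):
    """Relative field RMSE between two coefficient sets over given points."""
    from zflex.field import evaluate_field

    ge = evaluate_field(c_est, pts)
    gt = evaluate_field(c_true, pts)
    rms_t = np.sqrt((gt**2).sum(axis=1).mean())
    return np.sqrt(((ge - gt) ** 2).sum(axis=1).mean()) / rms_t
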