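import numpy as np
import pytest

from calvaria import fem
from calvaria.calibration import default_grid, sweep_suture_strain
from calvaria.meshing import tetrahedralize
from calvaria.morphology import segment_sutures
from calvaria.phantom import calibration_rig
from calvaria.pipeline import _map_to_tets, build_phantom_model, demo_morph, demo_spec


@pytest.fixture(scope="session")
def dome_skull():
    """Compact 4-plate dome, sutures+endocast+covers synthesized and meshed."""
    spec = demo_spec()
    return spec, build_phantom_model(spec, morph=demo_morph())


@pytest.fixture(scope="session")
def rig():
    """Three-beam calibration rig: volume, mesh, pair bookkeeping, load case."""
    vol, load_pt = calibration_rig()
    mesh = tetrahedralize(vol)
    pair_vol, pairs = segment_sutures(vol)
    tet_pair = _map_to_tets(mesh, pair_vol, 1)
    lc = fem.LoadCase(load_pt, disc_diameter=3.0, force=0.1, anterior_mode="all")
    return vol, mesh, tet_pair, pairs, lc


@pytest.fixture(scope="session")
def rig_curves(rig):
    """Bone-modulus sweep curves on the rig (25 log-spaced grid points)."""
    _, mesh, tet_pair, pairs, lc = rig
    grid = default_grid()
    curves = sweep_suture_strain(mesh, tet_pair, pairs, lc, grid)
    return grid, curves


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
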