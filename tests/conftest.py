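import numpy as np
import pytest

from emvalidate.fixtures import FixtureSpec, make_map_pair, make_model, perturb_model
from emvalidate.map_simulation import SimulationParams
from emvalidate.model_io import ca_coordinates
from emvalidate.volumetric_io import DensityGrid


@pytest.fixture(scope="session")
def helix_spec():
    return FixtureSpec(n_residues=20, geometry="ideal_helix", resolution=3.0,
                       noise_sd=0.1, voxel_size=1.0, seed=1)


@pytest.fixture(scope="session")
def helix_model(helix_spec):
    return make_model(helix_spec)


@pytest.fixture(scope="session")
def helix_maps(helix_model, helix_spec):
    """(clean, noisy) simulated maps for the 20-residue helix."""
    return make_map_pair(helix_model, helix_spec)


@pytest.fixture(scope="session")
def sim_params(helix_spec, helix_maps):
    return SimulationParams(resolution=helix_spec.resolution, grid_template=helix_maps[0])


def displace_residue(model, index, magnitude):
    """Translate residue ``index`` by ``magnitude`` Å radially away from the
    model centroid (so it lands in background, not on another chain segment)."""
    keys = list(model.residues)
    target = keys[index]
    cas = ca_coordinates(model)
    centroid = np.mean(list(cas.values()), axis=0)
    vec = np.asarray(cas[target]) - centroid
    vec = magnitude * vec / np.linalg.norm(vec)
    return perturb_model(model, [(target, vec)]), target


@pytest.fixture(scope="session")
def perturbed_helix(helix_model):
    """Helix with residue 10 displaced 8 Å into background, plus its key."""
    return displace_residue(helix_model, 9, 8.0)


def noise_grid(seed, shape=(48, 48, 48), mean=0.0, sd=1.0, voxel=1.0):
    rng = np.random.default_rng(seed)
    return DensityGrid(rng.normal(mean, sd, shape), (voxel,) * 3)
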