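import numpy as np
import pytest

from cubiphase.chi_params import chi_to_repulsion, default_chi_matrix
from cubiphase.dpd_engine import DPDParams, box_for_counts, init_system, run


@pytest.fixture(scope="session")
def chi_default():
    return default_chi_matrix()


@pytest.fixture(scope="session")
def a_default(chi_default):
    return chi_to_repulsion(chi_default)


@pytest.fixture(scope="session")
def a_uniform():
    """Repulsion matrix with no species contrast (athermal mixture)."""
    return np.full((5, 5), 25.0)


@pytest.fixture(scope="session")
def small_mixed_system():
    """~100-bead mixed system (A-B dimers + water) for force-oracle tests."""
    params = DPDParams(seed=11)
    counts = {"A": 20, "B": 20, "WATER": 60}
    box = box_for_counts(counts, rho=params.rho)
    return init_system(counts, box, params, seed=11), params


@pytest.fixture(scope="session")
def demixed_slab_run():
    """Strongly demixed two-species slab (interfaces normal to z): the
    positive-tension reference system."""
    import numpy as np

    from cubiphase.dpd_engine import BeadSystem

    rng = np.random.default_rng(4)
    n = 1500
    a = np.full((5, 5), 25.0)
    a[2, 4] = a[4, 2] = 80.0          # strong water/Met incompatibility
    box = box_for_counts({"WATER": n, "MET": n})
    pos = rng.uniform(0, 1, (2 * n, 3)) * box
    pos[:n, 2] = rng.uniform(0, box[2] / 2, n)
    pos[n:, 2] = rng.uniform(box[2] / 2, box[2], n)
    vel = rng.normal(0, 1, (2 * n, 3))
    vel -= vel.mean(axis=0)
    system = BeadSystem(box=box, positions=pos, velocities=vel,
                        types=np.array([2] * n + [4] * n),
                        bonds=np.empty((0, 2), int))
    params = DPDParams(seed=4, n_steps=4000, equil_steps=1000, sample_every=100)
    return run(system, params, a)


@pytest.fixture(scope="session")
def pure_water_run(a_uniform):
    """Pure-fluid reference run at the standard parameter set (session-shared:
    used for thermostat, momentum, tension-isotropy and pressure checks)."""
    params = DPDParams(seed=3, n_steps=6000, equil_steps=1500, sample_every=150)
    counts = {"WATER": 3000}
    box = box_for_counts(counts, rho=params.rho)
    system = init_system(counts, box, params, seed=3)
    traj = run(system, params, a_uniform)
    return traj, params
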