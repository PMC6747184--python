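import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from boostmd.conformation import compute_dihedrals, dihedral_pca
from boostmd.synthetic import (
    SyntheticMembraneSpec,
    SyntheticPeptideSpec,
    make_membrane_system,
    make_two_state_helix_trajectory,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def helix_ensemble():
    """600-frame two-state helix, p_bent = 0.5, fixed seed."""
    spec = SyntheticPeptideSpec(p_bent=0.5, n_frames=600, seed=42)
    return make_two_state_helix_trajectory(spec)


@pytest.fixture(scope="session")
def helix_dihedrals(helix_ensemble):
    traj, top, _ = helix_ensemble
    return compute_dihedrals(traj, top)


@pytest.fixture(scope="session")
def helix_pca(helix_dihedrals):
    return dihedral_pca(helix_dihedrals)


@pytest.fixture(scope="session")
def membrane_system():
    """150-frame pseudo-membrane with pore and a handful of waters."""
    spec = SyntheticMembraneSpec(n_frames=150, n_waters=20, seed=7)
    return make_membrane_system(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
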