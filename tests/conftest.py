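import numpy as np
import pytest

import chemoarch as ca


@pytest.fixture(scope="session")
def geometry():
    """60-region two-hemisphere spherical parcellation."""
    return ca.generate_parcellation(60, seed=11)


@pytest.fixture(scope="session")
def geometry100():
    """100-region parcellation matching the reference atlas resolution."""
    return ca.generate_parcellation(100, seed=11)


@pytest.fixture(scope="session")
def atlas60(geometry):
    atlas, truth = ca.generate_receptor_atlas(
        geometry, n_receptors=12, n_latent=1, noise_sd=0.2, seed=21
    )
    return atlas, truth


@pytest.fixture(scope="session")
def atlas100(geometry100):
    atlas, truth = ca.generate_receptor_atlas(
        geometry100, n_receptors=19, n_latent=1, noise_sd=0.2, seed=22
    )
    return atlas, truth


@pytest.fixture(scope="session")
def connectomes100(geometry100, atlas100):
    atlas, _ = atlas100
    sim = ca.receptor_similarity(atlas)
    sc, fc, truth = ca.generate_connectomes(
        geometry100, sim, density=0.2, coupling_beta=1.0, noise_sd=0.2, seed=31
    )
    return sc, fc, sim, truth


@pytest.fixture(scope="session")
def spins100(geometry100):
    return ca.build_spin_ensemble(geometry100, n_perm=500, seed=41)


@pytest.fixture(scope="session")
def spins60(geometry):
    return ca.build_spin_ensemble(geometry, n_perm=300, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
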