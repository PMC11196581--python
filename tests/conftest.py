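import numpy as np
import pytest

from sweetmsm import toysim


@pytest.fixture(scope="session")
def transporter_potential():
    return toysim.make_transporter_potential()


@pytest.fixture(scope="session")
def double_well():
    return toysim.make_transporter_potential(toysim.double_well_config())


@pytest.fixture(scope="session")
def topology():
    return toysim.make_toy_topology()


@pytest.fixture(scope="session")
def latent_short(transporter_potential):
    x0 = transporter_potential.centers[0]
    return toysim.simulate_langevin(transporter_potential, x0, n_steps=150, seed=42)


@pytest.fixture(scope="session")
def embedded(latent_short, topology):
    return toysim.embed_coordinates(latent_short, topology)


def harmonic_potential(k: float = 1.0, kT: float = toysim.KT_300K):
    """1-D harmonic well U = 1/2 k x^2 realized through the quadratic
    confining wall (zero-width domain at the origin, no basin depth)."""
    return toysim.ToyPotential(
        dim_names=("x",),
        basin_names=("origin",),
        centers=np.array([[0.0]]),
        depths=np.array([0.0]),
        widths=np.array([[1.0]]),
        periodic=np.array([False]),
        bounds=np.array([[0.0, 0.0]]),
        wall_k=k / 2.0,
        kT=kT,
    )
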