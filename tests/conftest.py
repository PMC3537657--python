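import numpy as np
import pytest

import titanoqsar as tq
from titanoqsar import mm_engine as mm
from titanoqsar import synthetic_data as sd


@pytest.fixture(scope="session")
def generic_ff():
    return mm.generic_forcefield()


@pytest.fixture(scope="session")
def activities():
    return tq.load_fixture("activities")


@pytest.fixture(scope="session")
def descriptor_records():
    return tq.load_fixture("descriptors")


@pytest.fixture(scope="session")
def energy_records():
    return tq.load_fixture("energies")


@pytest.fixture
def butane_like(generic_ff):
    """Four-carbon chain with one flexible central torsion."""
    coords = [[0.0, 0.0, 0.0], [1.53, 0.0, 0.0],
              [2.04, 1.44, 0.0], [3.57, 1.44, 0.10]]
    return tq.Molecule(elements=["C", "C", "C", "C"], coords=coords,
                       bonds=[(0, 1, 1), (1, 2, 1), (2, 3, 1)],
                       name="butane_like")


@pytest.fixture(scope="session")
def snug_toy_complex():
    """LJ ring slightly wider than the pair minimum: the cavity centre is
    a strict interior optimum for a single guest particle."""
    spec = sd.ToyComplexSpec(ring_radius=4.0)
    return sd.gen_toy_complex(spec)


def fd_gradient(mol, ff, coords=None, h=1e-5):
    """Central finite-difference gradient, the independent oracle for the
    analytic one."""
    if coords is None:
        coords = mol.coords
    out = np.zeros_like(coords)
    for i in range(mol.n_atoms):
        for d in range(3):
            cp = coords.copy()
            cm = coords.copy()
            cp[i, d] += h
            cm[i, d] -= h
            out[i, d] = (mm.energy(mol, ff, cp).energy
                         - mm.energy(mol, ff, cm).energy) / (2 * h)
    return out
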