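import numpy as np
import pytest

from bcrpsvm.chem_io import Molecule
from bcrpsvm.synthetic import toy_molecules


@pytest.fixture(scope="session")
def toys():
    """Name → Molecule map of the versioned toy fixtures."""
    return {c.structure.name: c.structure for c in toy_molecules()}


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation plus a translation."""
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10, 10, size=3)
    return q, t


def transformed(m: Molecule, q: np.ndarray, t: np.ndarray) -> Molecule:
    return Molecule(
        symbols=m.symbols,
        masses=m.masses,
        coords=m.coords @ q.T + t,
        bonds=m.bonds,
        name=m.name,
    )
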