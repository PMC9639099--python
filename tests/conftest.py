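import numpy as np
import pytest

from electrosorb import Environment, FixtureSpec, build_grid, toy_protein
from electrosorb.structure import Atom, Structure


@pytest.fixture(scope="session")
def toy():
    """Default charged toy protein (net −5 e, entry atom marked)."""
    return toy_protein(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def small_grid():
    """Coarse orientation grid (dθ = 30°, 6 equator samples) for fast scans."""
    return build_grid(dtheta=30.0, equator_count=6)


@pytest.fixture(scope="session")
def saline_env():
    return Environment(ionic_strength=0.15)


@pytest.fixture(scope="session")
def saltfree_env():
    return Environment(ionic_strength=0.0)


def make_structure(positions, charges, radii=None, et_serial=None):
    """Hand-rolled structure for pointwise checks."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    radii = np.full(n, 1.0) if radii is None else np.asarray(radii, float)
    atoms = [
        Atom(
            serial=i + 1,
            name=f"X{i}",
            residue_name="GLY",
            chain="A",
            residue_seq=i + 1,
            position=positions[i],
            charge=float(charges[i]),
            radius=float(radii[i]),
        )
        for i in range(n)
    ]
    return Structure(atoms, et_entry_serial=et_serial)
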