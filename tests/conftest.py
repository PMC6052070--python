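import numpy as np
import pytest

from saposim.hypermatrix import GridSpec
from saposim.molecules import orient_at_interface
from saposim.synthetic_data import FIXTURE_NAMES, fixture_molecule


@pytest.fixture(scope="session")
def oriented_fixtures():
    """All four fixture molecules, interface-oriented."""
    out = {}
    for name in FIXTURE_NAMES:
        mol = fixture_molecule(name)
        out[name] = mol.transformed(orient_at_interface(mol))
    return out


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec.coarse()


@pytest.fixture(scope="session")
def anti_butane():
    """Four-bead chain in the anti (trans) conformation, one rotatable torsion.

    Realistic bond geometry (1.53 Å bonds, 111° angles) so that the gauche
    grid points bring the 1-4 beads inside their vdW contact distance.
    """
    from saposim.molecules import molecule_from_arrays

    b, theta = 1.53, np.deg2rad(111.0)
    # zigzag in the xz plane with exact 111 degree angles: anti dihedral (180)
    d = b * np.sin(theta / 2), b * np.cos(theta / 2)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [d[0], 0.0, d[1]],
            [2 * d[0], 0.0, 0.0],
            [3 * d[0], 0.0, d[1]],
        ]
    )
    return molecule_from_arrays(
        "butane_like",
        ["C"] * 4,
        coords,
        bonds=[(0, 1), (1, 2), (2, 3)],
        rotatable_torsions=[(0, 1, 2, 3)],
    )
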