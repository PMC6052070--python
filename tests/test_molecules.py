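"""Structure input, parameterization, conformers, orientation, and areas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saposim.geometry import RigidTransform, rotation_z
from saposim.molecules import (
    CombinatorialCapError,
    ParameterizationError,
    accessible_surfaces,
    enumerate_conformations,
    interfacial_area,
    molecule_from_arrays,
    orient_at_interface,
    read_structure,
    write_pdb,
)
from saposim.synthetic_data import fixture_molecule, fixture_to_csv


# ---------------------------------------------------------------------------
# accessible surface
# ---------------------------------------------------------------------------

def test_sasa_isolated_sphere_is_analytic():
    s = accessible_surfaces(np.zeros((1, 3)), np.array([1.8]))
    assert s[0] == pytest.approx(4 * math.pi * (1.8 + 1.4) ** 2, rel=1e-12)


def test_sasa_buried_atom_loses_surface():
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    s = accessible_surfaces(coords, np.full(3, 1.8))
    lone = 4 * math.pi * (1.8 + 1.4) ** 2
    assert s[0] < s[1] < lone  # central bead most occluded


# ---------------------------------------------------------------------------
# read_structure
# ---------------------------------------------------------------------------

def test_read_single_carbon_atom_table(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("name,element,x,y,z\nC1,C,0,0,0\n")
    mol = read_structure(p)
    assert mol.heavy_atom_count == 1
    atom = mol.atoms[0]
    assert atom.radius == 1.8
    # carbon transfer energy is the per-area scale times the sphere surface
    assert atom.transfer_energy == pytest.approx(-0.105 * atom.accessible_surface)


def test_unknown_element_raises_parameterization_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("name,element,x,y,z\nX1,Xx,0,0,0\n")
    with pytest.raises(ParameterizationError, match="Xx"):
        read_structure(p)


def test_fixture_csv_heavy_atom_count(tmp_path):
    p = tmp_path / "chol.csv"
    fixture_to_csv("cholesterol_like", p)
    # count non-hydrogen rows of the written file independently
    rows = [ln.split(",")[1] for ln in p.read_text().splitlines()[1:]]
    expected = sum(1 for e in rows if e.upper() != "H")
    mol = read_structure(p)
    assert mol.heavy_atom_count == expected == 13


def test_pdb_round_trip(tmp_path):
    mol = fixture_molecule("delta7_like")
    p = tmp_path / "d7.pdb"
    write_pdb(mol, p)
    back = read_structure(p)
    assert len(back.atoms) == len(mol.atoms)
    assert np.allclose(back.coordinates(), mol.coordinates(), atol=5e-3)


def test_parameter_assignment_is_total():
    for name in ("dmpc_like", "frondoside_like"):
        mol = fixture_molecule(name)
        for a in mol.atoms:
            assert np.isfinite(a.partial_charge)
            assert np.isfinite(a.transfer_energy)
            assert a.accessible_surface >= 0
            assert a.radius > 0


# ---------------------------------------------------------------------------
# conformer enumeration
# ---------------------------------------------------------------------------

def test_rigid_molecule_yields_single_input_conformer():
    mol = molecule_from_arrays("dia", ["C", "O"], [[0, 0, 0], [1.4, 0, 0]])
    confs = enumerate_conformations(mol, step=60.0)
    assert len(confs) == 1
    assert np.allclose(confs[0].coordinates, mol.coordinates())


def test_butane_grid_ranks_anti_first(anti_butane):
    confs = enumerate_conformations(anti_butane, step=120.0)
    assert len(confs) == 3
    # offset 0 keeps the anti input geometry; gauche rotations bring the
    # terminal beads into vdW repulsion
    assert confs[0].torsion_angles == (0.0,)
    energies = sorted(c.internal_energy for c in confs)
    assert energies[0] == confs[0].internal_energy


def test_two_torsion_enumeration_is_exhaustive():
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.4, 0.6, 0.0], [2.8, 0.0, 0.0],
         [4.2, 0.6, 0.0], [5.6, 0.0, 0.0], [7.0, 0.6, 0.0]]
    )
    mol = molecule_from_arrays(
        "hex", ["C"] * 6, coords,
        bonds=[(i, i + 1) for i in range(5)],
        rotatable_torsions=[(0, 1, 2, 3), (2, 3, 4, 5)],
    )
    confs, rejected = enumerate_conformations(mol, step=90.0, return_rejected=True)
    assert len(confs) + rejected == 16
    assert len(confs) <= 16
    es = [c.internal_energy for c in confs]
    assert es == sorted(es)


def test_combinatorial_cap_refusal(anti_butane):
    with pytest.raises(CombinatorialCapError, match="cap"):
        enumerate_conformations(anti_butane, step=1.0, max_conformers=100)


# ---------------------------------------------------------------------------
# interface orientation
# ---------------------------------------------------------------------------

def test_diatomic_alignment_closed_form():
    mol = molecule_from_arrays("dia", ["C", "O"], [[0, 0, 0], [1.0, 0, 0]])
    t = orient_at_interface(mol)
    out = t.apply(mol.coordinates())
    assert np.allclose(out[:, :2], out[0, :2], atol=1e-9)  # both on one vertical
    assert out[0, 2] < out[1, 2]  # apolar atom lower
    assert np.allclose(np.linalg.norm(out[1] - out[0]), 1.0)


def test_orientation_is_idempotent():
    mol = fixture_molecule("frondoside_like")
    once = mol.transformed(orient_at_interface(mol))
    t2 = orient_at_interface(once)
    assert t2.is_identity(atol=1e-6)


def test_uniformly_apolar_molecule_warns_identity():
    mol = molecule_from_arrays("cc", ["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    with pytest.warns(UserWarning, match="amphiphilic"):
        t = orient_at_interface(mol)
    assert t.is_identity()


# ---------------------------------------------------------------------------
# interfacial area
# ---------------------------------------------------------------------------

def test_single_atom_disk_area_is_analytic():
    mol = molecule_from_arrays("c", ["C"], [[0, 0, 0]])
    area = interfacial_area(mol, RigidTransform.identity())
    assert area == pytest.approx(math.pi * 1.8**2, rel=5e-3)


def test_union_semantics_disjoint_and_coincident():
    two_far = molecule_from_arrays("f", ["C", "C"], [[0, 0, 0], [10.0, 0, 0]])
    afar = interfacial_area(two_far, RigidTransform.identity())
    assert afar == pytest.approx(2 * math.pi * 1.8**2, rel=5e-3)
    two_same = molecule_from_arrays("s", ["C", "C"], [[0, 0, 0], [0, 0, 0.2]])
    asame = interfacial_area(two_same, RigidTransform.identity())
    assert asame == pytest.approx(math.pi * 1.8**2, rel=5e-3)


def test_area_monotone_under_atom_addition():
    small = molecule_from_arrays("a", ["C", "C"], [[0, 0, 0], [2.5, 0, 0]])
    bigger = molecule_from_arrays("b", ["C", "C", "C"], [[0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]])
    t = RigidTransform.identity()
    assert interfacial_area(bigger, t) >= interfacial_area(small, t) - 1e-9


@settings(max_examples=20, deadline=None, derandomize=True)
@given(angle=st.floats(0, 360), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
def test_area_invariant_under_z_rotation_and_xy_translation(angle, dx, dy):
    mol = fixture_molecule("delta7_like")
    base = orient_at_interface(mol)
    moved = RigidTransform(
        rotation=rotation_z(angle), translation=np.array([dx, dy, 0.0])
    ).compose(base)
    a0 = interfacial_area(mol, base)
    a1 = interfacial_area(mol, moved)
    assert a1 == pytest.approx(a0, rel=0.02)


def test_sterol_fixture_area_ordering(oriented_fixtures):
    a_chol = interfacial_area(oriented_fixtures["cholesterol_like"])
    a_d7 = interfacial_area(oriented_fixtures["delta7_like"])
    assert a_d7 > a_chol  # the L-shaped sterol projects the wider footprint
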