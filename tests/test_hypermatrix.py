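"""Pair energies, docking search, assemblies, and the interaction matrix."""

import math

import numpy as np
import pytest

from saposim.forcefield import COULOMB_KJ_A, DEFAULT_FF
from saposim.geometry import RigidTransform
from saposim.hypermatrix import (
    GridSpec,
    IncompleteMatrixError,
    InteractionMatrix,
    build_assembly,
    build_interaction_matrix,
    dock_pair,
    pair_energy,
    pose_transform,
)
from saposim.molecules import molecule_from_arrays


def _atom(element="C", charge=None, pos=(0, 0, 0)):
    charges = None if charge is None else [charge]
    return molecule_from_arrays("a", [element], [list(pos)], charges=charges)


def _translation(x, y=0.0, z=0.0):
    return RigidTransform(translation=np.array([x, y, z], dtype=float))


# ---------------------------------------------------------------------------
# pair energy
# ---------------------------------------------------------------------------

def test_all_components_vanish_at_long_range():
    e = pair_energy(_atom(), _atom(), _translation(100.0))
    assert abs(e.vdw) < 1e-6
    assert e.electrostatic == 0.0
    assert e.hydrophobic == 0.0
    assert e.total == e.vdw + e.electrostatic + e.hydrophobic


def test_coulomb_closed_form_at_5A():
    a = _atom("O", charge=1.0)
    b = _atom("O", charge=-1.0)
    e = pair_energy(a, b, _translation(5.0))
    # k·q1·q2/(3r·r) with k = 1389.35458 kJ·Å/mol
    assert e.electrostatic == pytest.approx(COULOMB_KJ_A * -1.0 / (3.0 * 25.0), rel=1e-12)
    assert e.electrostatic < 0


def test_pair_energy_symmetric_under_role_swap():
    a = molecule_from_arrays("a", ["C", "O"], [[0, 0, 0], [1.4, 0, 0]])
    b = molecule_from_arrays("b", ["C", "C"], [[0, 0, 0], [0, 1.5, 0]])
    pose = RigidTransform(translation=np.array([4.0, 1.0, 0.5]))
    e_ab = pair_energy(a, b, pose)
    e_ba = pair_energy(b, a, pose.inverse())
    assert e_ab.total == pytest.approx(e_ba.total, rel=1e-10)
    assert e_ab.vdw == pytest.approx(e_ba.vdw, rel=1e-10)


def test_overlapping_atoms_rejected_with_sentinel():
    e = pair_energy(_atom(), _atom(), _translation(1.0))  # < 0.7·(1.8+1.8)
    assert not np.isfinite(e.total)


def test_breakdown_identity_and_normalization():
    a = molecule_from_arrays("a", ["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    b = _atom()
    e = pair_energy(a, b, _translation(4.0))
    assert e.total == e.vdw + e.electrostatic + e.hydrophobic
    assert e.per_heavy_atom_total == pytest.approx(e.total / 3)


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

def _brute_force_dock(central, ligand, search, top_k=50):
    """Independent pose-by-pose enumeration of the identical grid."""
    results = []
    for idx, spin, az, d, dz in search.poses():
        e = pair_energy(central, ligand, pose_transform(spin, az, d, dz))
        if np.isfinite(e.total):
            results.append((e.total, idx))
    results.sort()
    return results[:top_k]


def test_dock_pair_matches_brute_force_oracle():
    central = _atom()
    ligand = _atom()
    search = GridSpec(radial=tuple(np.arange(2.0, 8.5, 0.5)), n_azimuth=8, n_spin=4)
    oracle = _brute_force_dock(central, ligand, search)
    found = dock_pair(central, ligand, search, top_k=50)
    assert len(found) == len(oracle)
    for pose, (e_ref, idx_ref) in zip(found, oracle):
        assert pose.grid_index == idx_ref
        assert pose.energy.total == pytest.approx(e_ref, rel=1e-9)


def test_grid_refinement_never_worsens_best_energy():
    central = _atom()
    ligand = _atom()
    coarse = GridSpec(radial=tuple(np.arange(2.0, 8.1, 1.0)), n_azimuth=4, n_spin=2, z_offsets=(0.0,))
    fine = GridSpec(radial=tuple(np.arange(2.0, 8.05, 0.5)), n_azimuth=8, n_spin=2, z_offsets=(0.0,))
    e_coarse = dock_pair(central, ligand, coarse, top_k=1)[0].energy.total
    e_fine = dock_pair(central, ligand, fine, top_k=1)[0].energy.total
    assert e_fine <= e_coarse + 1e-12


def test_self_docking_role_invariance():
    dia = molecule_from_arrays("dia", ["C", "C"], [[0, 0, -0.75], [0, 0, 0.75]])
    search = GridSpec(radial=(3.0, 4.0, 5.0), n_azimuth=6, n_spin=6, z_offsets=(0.0,))
    e1 = dock_pair(dia, dia, search, top_k=1)[0].energy.total
    e2 = dock_pair(dia, dia, search, top_k=1)[0].energy.total
    assert e1 == pytest.approx(e2, rel=1e-12)


def test_saponin_lipid_docking_ordering(oriented_fixtures, coarse_grid):
    sap = oriented_fixtures["frondoside_like"]
    per_heavy = {}
    for name in ("dmpc_like", "cholesterol_like", "delta7_like"):
        best = dock_pair(sap, oriented_fixtures[name], coarse_grid, top_k=1)[0]
        per_heavy[name] = best.energy.per_heavy_atom_total
        # neutral-lipid docking is hydrophobically dominated
        assert abs(best.energy.hydrophobic) > abs(best.energy.electrostatic)
    assert (
        per_heavy["dmpc_like"]
        < per_heavy["cholesterol_like"]
        < per_heavy["delta7_like"]
        < 0.0
    )


def test_all_poses_clashing_returns_empty():
    search = GridSpec(radial=(1.0,), n_azimuth=2, n_spin=1, z_offsets=(0.0,))
    with pytest.warns(UserWarning, match="clash"):
        assert dock_pair(_atom(), _atom(), search) == []


# ---------------------------------------------------------------------------
# assemblies
# ---------------------------------------------------------------------------

def test_assembly_of_one_reduces_to_dock_pair(coarse_grid):
    a, b = _atom(), _atom()
    search = GridSpec(radial=(3.0, 3.6, 4.5), n_azimuth=6, n_spin=2, z_offsets=(0.0,))
    poses, energies, mean_e = build_assembly(a, b, n=1, search=search)
    best = dock_pair(a, b, search, top_k=1)[0]
    assert energies[0] == pytest.approx(best.energy.total, rel=1e-12)


def test_assembly_energies_account_for_prior_ligands():
    # second ligand must avoid the first's site and sees its field
    a, b = _atom(), _atom()
    search = GridSpec(radial=(3.6,), n_azimuth=8, n_spin=1, z_offsets=(0.0,))
    poses, energies, _ = build_assembly(a, b, n=2, search=search)
    assert len(poses) == 2
    p0 = poses[0].translation
    p1 = poses[1].translation
    assert np.linalg.norm(p1 - p0) > 2.5  # distinct, non-clashing sites
    # with only attraction available, adding a ligand never costs energy
    assert energies[1] <= 1e-9


def test_assembly_truncates_when_no_site_left():
    a, b = _atom(), _atom()
    search = GridSpec(radial=(3.6,), n_azimuth=1, n_spin=1, z_offsets=(0.0,))
    with pytest.warns(UserWarning, match="truncated"):
        poses, energies, _ = build_assembly(a, b, n=3, search=search)
    assert len(poses) < 3


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------

def test_identical_types_give_constant_matrix():
    a = molecule_from_arrays("a", ["C", "C"], [[0, 0, -0.75], [0, 0, 0.75]])
    b = molecule_from_arrays("b", ["C", "C"], [[0, 0, -0.75], [0, 0, 0.75]])
    search = GridSpec(radial=(3.0, 3.6, 4.5), n_azimuth=4, n_spin=2, z_offsets=(0.0,))
    M = build_interaction_matrix({"A": a, "B": b}, search)
    assert np.allclose(M.energies, M.energies[0, 0])
    assert np.array_equal(M.energies, M.energies.T)


def test_matrix_requires_symmetry_and_square():
    with pytest.raises(ValueError):
        InteractionMatrix(types=("A", "B"), energies=np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_matrix_csv_round_trip(tmp_path):
    M = InteractionMatrix(
        types=("A", "B"), energies=np.array([[-1.0, 0.25], [0.25, -2.0]])
    )
    p = tmp_path / "m.csv"
    M.to_csv(p)
    back = InteractionMatrix.from_csv(p)
    assert back.types == M.types
    assert np.allclose(back.energies, M.energies)


def test_fixture_matrix_saponin_prefers_phospholipid(oriented_fixtures, coarse_grid):
    mols = {
        "DMPC": oriented_fixtures["dmpc_like"],
        "CHOL": oriented_fixtures["cholesterol_like"],
        "SAP": oriented_fixtures["frondoside_like"],
    }
    M = build_interaction_matrix(mols, coarse_grid)
    assert M.energy("SAP", "DMPC") < M.energy("SAP", "CHOL")
    assert np.array_equal(M.energies, M.energies.T)


def test_incomplete_pair_refuses_matrix():
    far = GridSpec(radial=(1.0,), n_azimuth=2, n_spin=1, z_offsets=(0.0,))
    with pytest.raises(IncompleteMatrixError), pytest.warns(UserWarning):
        build_interaction_matrix({"A": _atom(), "B": _atom()}, far)
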