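"""Implicit-bilayer insertion profiling.

The bilayer is represented by the empirical hydration function

    C(z) = 1 − 1 / (1 + exp(α·(|z| − z₀)))

which rises from ≈0 at the hydrophobic core (z = 0) to ≈1 in bulk water, with
α = 1.99 and the hydrophilic/hydrophobic interface at |z| = z₀.  The total
bilayer thickness is 36 Å, so the membrane spans |z| ≤ 18 Å with the
polar-head/alkyl-chain interface at z₀ = 13.5 Å by default.

A molecule's position is scored by two restraints:

* hydrophobic restraint  E_pho = −Σᵢ S(i)·etrᵢ·C(zᵢ)  — apolar atoms
  (etr < 0) are penalized in water and polar atoms rewarded there;
* lipid-perturbation restraint  E_lip = a_lip·Σᵢ S(i)·(1 − C(zᵢ)) — every
  atom pays for the bilayer volume it perturbs.

The insertion scan translates the molecule's center of mass along z 1 Å at a
time and rotates it through an exhaustive orientation grid at each depth,
keeping the minimum restraint sum: an "energy-like" profile whose global
minimum is the most stable membrane position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from saposim.geometry import RigidTransform, euler_zyz
from saposim.molecules import ParameterizedMolecule

#: default per-surface lipid perturbation constant, kJ mol⁻¹ Å⁻²
DEFAULT_A_LIP = 0.018


@dataclass(frozen=True)
class ImplicitMembrane:
    """Implicit bilayer: properties vary only along the normal (z) axis."""

    alpha: float = 1.99  # steepness of the hydration transition
    z0: float = 13.5  # hydrophilic/hydrophobic interface, Å
    half_thickness: float = 18.0  # total bilayer thickness 36 Å
    lipid_perturbation_coeff: float = DEFAULT_A_LIP  # a_lip, kJ/(mol·Å²)

    def __post_init__(self):
        if not (0 < self.z0 < self.half_thickness):
            raise ValueError("z0 must satisfy 0 < z0 < half_thickness")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class Pose:
    """Position of a rigid molecule in the membrane frame."""

    z_center: float  # center of mass along the membrane normal, Å
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # ZYZ angles

    def transform(self, center: np.ndarray) -> RigidTransform:
        """Rigid move rotating about ``center`` then centering the molecule at z_center."""
        R = euler_zyz(*self.euler_deg)
        t = np.array([0.0, 0.0, self.z_center]) - R @ np.asarray(center, dtype=float)
        return RigidTransform(rotation=R, translation=t)


@dataclass(frozen=True)
class InsertionProfile:
    z_grid: np.ndarray  # center-of-mass depths, Å
    min_energy: np.ndarray  # kJ/mol, minimum over orientations per depth
    best_pose: tuple[Pose, ...]  # optimal pose per depth
    global_best: Pose
    global_best_energy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z_grid, "e_total": self.min_energy})


def hydration(z, mem: ImplicitMembrane):
    """C(z) = 1 − 1/(1 + e^(α(|z|−z₀))) ∈ (0,1), increasing in |z|."""
    z = np.asarray(z, dtype=float)
    out = 1.0 - 1.0 / (1.0 + np.exp(mem.alpha * (np.abs(z) - mem.z0)))
    return float(out) if out.ndim == 0 else out


def restraint_components(
    surfaces: np.ndarray,
    etr_scales: np.ndarray,
    z: np.ndarray,
    mem: ImplicitMembrane,
):
    """(hydrophobic, lipid-perturbation) restraints for atom depths ``z``.

    ``z`` may carry leading broadcast axes; the atom axis is last.
    """
    C = 1.0 - 1.0 / (1.0 + np.exp(mem.alpha * (np.abs(z) - mem.z0)))
    e_pho = -(surfaces * etr_scales * C).sum(axis=-1)
    e_lip = mem.lipid_perturbation_coeff * (surfaces * (1.0 - C)).sum(axis=-1)
    return e_pho, e_lip


def restraint_energy(
    mol: ParameterizedMolecule, pose: Pose, mem: ImplicitMembrane
) -> tuple[float, float, float]:
    """(total, hydrophobic, lipid-perturbation) restraint energies, kJ/mol."""
    coords = mol.coordinates()
    center = coords.mean(axis=0)
    z = pose.transform(center).apply(coords)[:, 2]
    e_pho, e_lip = restraint_components(mol.surfaces(), mol.etr_scales(), z, mem)
    return float(e_pho + e_lip), float(e_pho), float(e_lip)


def _orientation_grid(angular_step: float) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Atom z-offsets only depend on Ry(β)Rz(α); γ is dropped.

    The (β, α) grid covers full turns so it is closed under the in-plane flip
    (β, α) → (180°−β, α+180°) that negates every z offset — this makes the
    scanned profile exactly symmetric in z.
    """
    if angular_step <= 0 or 360.0 % angular_step != 0:
        raise ValueError("angular_step must be a positive divisor of 360")
    n = int(round(360.0 / angular_step))
    angles = [i * angular_step for i in range(n)]
    return angles


def insertion_scan(
    mol: ParameterizedMolecule,
    mem: ImplicitMembrane,
    dz: float = 1.0,
    angular_step: float = 30.0,
    margin: float = 18.0,
) -> InsertionProfile:
    """Exhaustive z-translation / rotation scan of the restraint energy.

    The center of mass is swept from −(half_thickness+margin) to
    +(half_thickness+margin) in steps of ``dz``; at each depth the molecule is
    rotated through the full ZYZ Euler grid at ``angular_step`` and the minimum
    restraint sum kept.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    angles = _orientation_grid(angular_step)
    if not angles:
        raise ValueError("empty rotation grid")
    coords = mol.coordinates()
    center = coords.mean(axis=0)
    rel = coords - center
    # z offset of each atom for each (beta, alpha): last row of Ry(b)Rz(a)
    betas = np.deg2rad(np.array(angles))
    alphas = np.deg2rad(np.array(angles))
    # (Ry(b)Rz(a) x)_z = -sin(b)*(cos(a)x - sin(a)y) + cos(b)z
    ca, sa = np.cos(alphas), np.sin(alphas)
    cb, sb = np.cos(betas), np.sin(betas)
    # u: (n_alpha, natoms) in-plane x after Rz(a)
    u = np.outer(ca, rel[:, 0]) - np.outer(sa, rel[:, 1])
    dzs = -sb[:, None, None] * u[None, :, :] + cb[:, None, None] * rel[:, 2][None, None, :]
    # dzs shape: (n_beta, n_alpha, natoms)
    zmax = mem.half_thickness + margin
    n_steps = int(round(2 * zmax / dz))
    z_grid = -zmax + dz * np.arange(n_steps + 1)
    S = mol.surfaces()
    etr = mol.etr_scales()
    min_e = np.empty(len(z_grid))
    best = []
    nb, na = len(angles), len(angles)
    flat = dzs.reshape(nb * na, -1)
    for idx, zc in enumerate(z_grid):
        z_atoms = flat + zc  # (n_orient, natoms)
        e_pho, e_lip = restraint_components(S, etr, z_atoms, mem)
        tot = e_pho + e_lip
        k = int(np.argmin(tot))
        min_e[idx] = tot[k]
        best.append(Pose(float(zc), (float(angles[k % na]), float(angles[k // na]), 0.0)))
    g = int(np.argmin(min_e))
    return InsertionProfile(
        z_grid=z_grid,
        min_energy=min_e,
        best_pose=tuple(best),
        global_best=best[g],
        global_best_energy=float(min_e[g]),
    )


def profile_to_csv(profile: InsertionProfile, mol: ParameterizedMolecule, mem: ImplicitMembrane, path) -> None:
    """Profile CSV with columns z, e_total, e_pho, e_lip (best pose per depth)."""
    rows = []
    for z, pose in zip(profile.z_grid, profile.best_pose):
        tot, pho, lip = restraint_energy(mol, pose, mem)
        rows.append({"z": z, "e_total": tot, "e_pho": pho, "e_lip": lip})
    pd.DataFrame(rows).to_csv(path, index=False)
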