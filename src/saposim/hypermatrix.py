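"""Pairwise docking at the hydrophobic/hydrophilic interface.

A central molecule is fixed at the interface (z = 0 plane) and a ligand,
likewise interface-oriented, is moved around it through interface-preserving
moves only: azimuthal position, radial distance, spin about its own z axis,
and a small vertical offset.  Every pose of the grid is scored with the
empirical pairwise field (6-12 van der Waals, Coulomb with ε(r) = 3r, and an
apolar contact term), and energies are normalized per heavy atom of the pair
so molecules of different size are comparable.  Best-pose per-heavy-atom
energies over all molecule-type pairs form the interaction matrix that drives
the lattice monolayer simulation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from saposim.forcefield import COULOMB_KJ_A, DEFAULT_FF, ForceFieldConfig
from saposim.geometry import RigidTransform, rotation_z
from saposim.molecules import ParameterizedMolecule

CLASH_SENTINEL = np.inf


@dataclass(frozen=True)
class EnergyBreakdown:
    """Docking energy split into its three components, kJ/mol."""

    vdw: float
    electrostatic: float
    hydrophobic: float
    n_heavy_pair: int  # heavy atoms of both partners (normalization divisor)

    @property
    def total(self) -> float:
        return self.vdw + self.electrostatic + self.hydrophobic

    @property
    def per_heavy_atom_total(self) -> float:
        return self.total / self.n_heavy_pair


@dataclass(frozen=True)
class DockedPose:
    """Ligand placement relative to the interface-fixed central molecule."""

    transform: RigidTransform
    energy: EnergyBreakdown
    grid_index: int = -1


@dataclass(frozen=True)
class GridSpec:
    """Interface-preserving pose grid.

    Cardinality = n_azimuth · n_spin · len(radial) · len(z_offsets); the
    production preset exceeds 10⁷ poses, the coarse preset is ~10⁴ and is what
    the tests and the analysis drivers use.
    """

    radial: tuple[float, ...]  # center-to-center distances, Å
    n_azimuth: int = 12
    n_spin: int = 12
    z_offsets: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)

    @property
    def cardinality(self) -> int:
        return self.n_azimuth * self.n_spin * len(self.radial) * len(self.z_offsets)

    @staticmethod
    def coarse() -> "GridSpec":
        return GridSpec(radial=tuple(np.arange(2.0, 12.5, 0.5)))

    @staticmethod
    def production() -> "GridSpec":
        return GridSpec(
            radial=tuple(np.arange(2.0, 14.0, 0.3)),
            n_azimuth=72,
            n_spin=72,
            z_offsets=tuple(np.linspace(-3.0, 3.0, 49)),
        )

    def poses(self):
        """Yield (index, spin_deg, azimuth_deg, distance, dz) lexicographically."""
        idx = 0
        for spin_i in range(self.n_spin):
            spin = 360.0 * spin_i / self.n_spin
            for az_i in range(self.n_azimuth):
                az = 360.0 * az_i / self.n_azimuth
                for d in self.radial:
                    for dz in self.z_offsets:
                        yield idx, spin, az, d, dz
                        idx += 1


def pose_transform(spin_deg: float, azimuth_deg: float, distance: float, dz: float) -> RigidTransform:
    a = math.radians(azimuth_deg)
    return RigidTransform(
        rotation=rotation_z(spin_deg),
        translation=np.array([distance * math.cos(a), distance * math.sin(a), dz]),
    )


# ---------------------------------------------------------------------------
# pair energy
# ---------------------------------------------------------------------------

def _pair_tables(a: ParameterizedMolecule, b: ParameterizedMolecule, cfg: ForceFieldConfig):
    """Precomputed per-pair constants reused across poses."""
    ra, rb = a.radii(), b.radii()
    sigma = ra[:, None] + rb[None, :]
    heavy = a.heavy_mask()[:, None] & b.heavy_mask()[None, :]
    qq = a.charges()[:, None] * b.charges()[None, :]
    sa, sb_ = a.etr_scales(), b.etr_scales()
    apolar = (sa[:, None] < 0) & (sb_[None, :] < 0)
    setr_a = a.surfaces() * np.abs(sa)
    setr_b = b.surfaces() * np.abs(sb_)
    pho_pair = -cfg.hydrophobic_weight * (setr_a[:, None] + setr_b[None, :])
    return sigma, heavy, qq, apolar, pho_pair


def _energies_for_positions(
    coords_a: np.ndarray,
    positions_b: np.ndarray,
    tables,
    cfg: ForceFieldConfig,
):
    """Vectorized components for ligand coordinates of shape (..., nb, 3).

    Returns (vdw, elec, pho, clash) with the leading broadcast shape.
    """
    sigma, heavy, qq, apolar, pho_pair = tables
    diff = positions_b[..., None, :, :] - coords_a[:, None, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    r = np.maximum(r, 1e-9)
    clash = (r < cfg.clash_factor * sigma).any(axis=(-2, -1))
    x = (sigma / r) ** 6
    vdw = np.where(heavy, cfg.vdw_epsilon * (x * x - 2.0 * x), 0.0).sum(axis=(-2, -1))
    elec = (COULOMB_KJ_A * qq / (cfg.dielectric_slope * r * r)).sum(axis=(-2, -1))
    taper = np.where(r < sigma + cfg.contact_margin, np.minimum((sigma / r) ** 6, 1.0), 0.0)
    pho = np.where(apolar, pho_pair * taper, 0.0).sum(axis=(-2, -1))
    return vdw, elec, pho, clash


def pair_energy(
    a: ParameterizedMolecule,
    b: ParameterizedMolecule,
    pose: RigidTransform,
    cfg: ForceFieldConfig = DEFAULT_FF,
) -> EnergyBreakdown:
    """Interaction energy of ``b`` placed by ``pose`` relative to ``a``.

    Overlapping atoms (r < clash_factor·(rᵢ+rⱼ)) make the pose invalid; all
    components are then the +inf sentinel.
    """
    tables = _pair_tables(a, b, cfg)
    pos_b = pose.apply(b.coordinates())
    vdw, elec, pho, clash = _energies_for_positions(a.coordinates(), pos_b, tables, cfg)
    n_heavy = a.heavy_atom_count + b.heavy_atom_count
    if clash:
        return EnergyBreakdown(CLASH_SENTINEL, CLASH_SENTINEL, CLASH_SENTINEL, n_heavy)
    return EnergyBreakdown(float(vdw), float(elec), float(pho), n_heavy)


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

def dock_pair(
    central: ParameterizedMolecule,
    ligand: ParameterizedMolecule,
    search: GridSpec | None = None,
    cfg: ForceFieldConfig = DEFAULT_FF,
    top_k: int = 50,
) -> list[DockedPose]:
    """Exhaustive interface-preserving docking of ``ligand`` around ``central``.

    Returns the ``top_k`` non-clashing poses sorted ascending by total energy
    (ties broken by grid index, so the result is deterministic and matches a
    brute-force enumeration of the same grid pose-for-pose).
    """
    search = search or GridSpec.coarse()
    tables = _pair_tables(central, ligand, cfg)
    coords_a = central.coordinates()
    coords_b = ligand.coordinates()
    spin_angles = [360.0 * i / search.n_spin for i in range(search.n_spin)]
    az_angles = [360.0 * i / search.n_azimuth for i in range(search.n_azimuth)]
    # translations for one spin block, in pose iteration order
    trans = np.array(
        [
            [d * math.cos(math.radians(az)), d * math.sin(math.radians(az)), dz]
            for az in az_angles
            for d in search.radial
            for dz in search.z_offsets
        ]
    )
    block = len(trans)
    records = []  # (total, grid_index, spin, az, d, dz, vdw, elec, pho)
    for si, spin in enumerate(spin_angles):
        rot_b = coords_b @ rotation_z(spin).T
        positions = rot_b[None, :, :] + trans[:, None, :]
        vdw, elec, pho, clash = _energies_for_positions(coords_a, positions, tables, cfg)
        tot = vdw + elec + pho
        ok = ~clash
        idx = np.nonzero(ok)[0]
        for k in idx:
            records.append(
                (float(tot[k]), si * block + int(k), float(vdw[k]), float(elec[k]), float(pho[k]))
            )
    if not records:
        warnings.warn("all poses clash; docking produced no valid pose", stacklevel=2)
        return []
    records.sort(key=lambda t: (t[0], t[1]))
    n_heavy = central.heavy_atom_count + ligand.heavy_atom_count
    out = []
    grid_params = {i: (spin, az, d, dz) for i, spin, az, d, dz in search.poses()} if top_k else {}
    for tot, gi, vdw, elec, pho in records[:top_k]:
        spin, az, d, dz = grid_params[gi]
        out.append(
            DockedPose(
                transform=pose_transform(spin, az, d, dz),
                energy=EnergyBreakdown(vdw, elec, pho, n_heavy),
                grid_index=gi,
            )
        )
    return out


def build_assembly(
    central: ParameterizedMolecule,
    ligand: ParameterizedMolecule,
    n: int,
    search: GridSpec | None = None,
    cfg: ForceFieldConfig = DEFAULT_FF,
):
    """Greedy sequential placement of ``n`` ligands around the central molecule.

    Ligand k takes the lowest-energy non-clashing pose given the central
    molecule and the k−1 ligands already placed (steric and energetic
    constraints of prior placements included).  Returns (poses, energies,
    mean_energy); the assembly is truncated with a warning when no
    non-clashing pose remains.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    search = search or GridSpec.coarse()
    placed_coords: list[np.ndarray] = []
    placed_poses: list[RigidTransform] = []
    energies: list[float] = []
    coords_b = ligand.coordinates()
    spin_angles = [360.0 * i / search.n_spin for i in range(search.n_spin)]
    az_angles = [360.0 * i / search.n_azimuth for i in range(search.n_azimuth)]
    trans = np.array(
        [
            [d * math.cos(math.radians(az)), d * math.sin(math.radians(az)), dz]
            for az in az_angles
            for d in search.radial
            for dz in search.z_offsets
        ]
    )
    tables_central = _pair_tables(central, ligand, cfg)
    tables_self = _pair_tables(ligand, ligand, cfg)
    block = len(trans)
    for k in range(n):
        best = None  # (tot, grid_index, transform)
        for si, spin in enumerate(spin_angles):
            rot_b = coords_b @ rotation_z(spin).T
            positions = rot_b[None, :, :] + trans[:, None, :]
            vdw, elec, pho, clash = _energies_for_positions(
                central.coordinates(), positions, tables_central, cfg
            )
            tot = vdw + elec + pho
            for prev in placed_coords:
                v2, e2, p2, c2 = _energies_for_positions(prev, positions, tables_self, cfg)
                tot = tot + v2 + e2 + p2
                clash = clash | c2
            tot = np.where(clash, np.inf, tot)
            k_best = int(np.argmin(tot))
            if np.isfinite(tot[k_best]) and (best is None or tot[k_best] < best[0]):
                az_i = k_best // (len(search.radial) * len(search.z_offsets))
                rem = k_best % (len(search.radial) * len(search.z_offsets))
                d_i, dz_i = divmod(rem, len(search.z_offsets))
                tf = pose_transform(
                    spin,
                    az_angles[az_i],
                    search.radial[d_i],
                    search.z_offsets[dz_i],
                )
                best = (float(tot[k_best]), si * block + k_best, tf)
        if best is None:
            warnings.warn(f"assembly truncated at {k} ligands: no non-clashing pose", stacklevel=2)
            break
        placed_poses.append(best[2])
        placed_coords.append(best[2].apply(coords_b))
        energies.append(best[0])
    mean_e = float(np.mean(energies)) if energies else float("nan")
    return placed_poses, energies, mean_e


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------

class IncompleteMatrixError(RuntimeError):
    """Raised when a pair docking failed and the matrix cannot be written."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric per-heavy-atom interaction energies for molecule-type pairs."""

    types: tuple[str, ...]
    energies: np.ndarray  # (n_types, n_types), kJ/mol per heavy atom

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (len(self.types), len(self.types)):
            raise ValueError("energies must be square over the type list")
        if not np.allclose(e, e.T, atol=1e-12):
            raise ValueError("interaction matrix must be symmetric")

    def energy(self, a: str, b: str) -> float:
        ia, ib = self.types.index(a), self.types.index(b)
        return float(self.energies[ia, ib])

    def lookup_array(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        order = order or self.types
        idx = [self.types.index(t) for t in order]
        return np.asarray(self.energies, dtype=float)[np.ix_(idx, idx)]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-heavy-atom interaction energies, kJ/mol\n")
            pd.DataFrame(self.energies, index=self.types, columns=self.types).to_csv(fh)

    @staticmethod
    def from_csv(path) -> "InteractionMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        types = tuple(str(t) for t in df.columns)
        e = df.to_numpy(dtype=float)
        e = 0.5 * (e + e.T)  # guard against formatting round-off
        return InteractionMatrix(types=types, energies=e)


def build_interaction_matrix(
    mols: dict[str, ParameterizedMolecule],
    search: GridSpec | None = None,
    cfg: ForceFieldConfig = DEFAULT_FF,
) -> InteractionMatrix:
    """Per-heavy-atom best-pose energies for every unordered molecule-type pair.

    Each pair is docked with both role assignments (a central / b ligand and
    vice versa) and the two best per-heavy-atom totals averaged, which
    symmetrizes the grid anisotropy.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecule types")
    types = tuple(mols)
    n = len(types)
    E = np.zeros((n, n))
    for i, j in itertools.combinations_with_replacement(range(n), 2):
        a, b = mols[types[i]], mols[types[j]]
        best_ab = dock_pair(a, b, search, cfg, top_k=1)
        best_ba = best_ab if i == j else dock_pair(b, a, search, cfg, top_k=1)
        if not best_ab or not best_ba:
            raise IncompleteMatrixError(
                f"docking failed for pair ({types[i]}, {types[j]}); matrix incomplete"
            )
        e = 0.5 * (
            best_ab[0].energy.per_heavy_atom_total + best_ba[0].energy.per_heavy_atom_total
        )
        E[i, j] = E[j, i] = e
    return InteractionMatrix(types=types, energies=E)
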