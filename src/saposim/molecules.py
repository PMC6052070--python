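"""Molecular structures with per-atom physicochemical parameters.

A :class:`ParameterizedMolecule` carries, per atom, a partial charge, a
transfer energy E_tr(i) (hydrophobicity, kJ/mol), an accessible surface S(i)
(Å²) and a van der Waals radius — everything the insertion restraints and the
docking energy need.  Structures come from PDB coordinate records, from a
plain CSV atom table, or from the synthetic fixture builders.

Transfer energies are parameterized per unit accessible surface: the parameter
table stores an atomic scale ``etr_per_area`` (kJ·mol⁻¹·Å⁻²) and the per-atom
transfer energy is E_tr(i) = etr_per_area · S(i).  Negative scales mark apolar
atoms (transfer from water into an apolar phase releases energy), positive
scales polar ones.

Coordinate convention: Å, right-handed, interface normal = +z, hydrophobic
side below z = 0, membrane center at z = 0.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from saposim.forcefield import (
    DEFAULT_FF,
    INTRAMOLECULAR_FF,
    ForceFieldConfig,
    coulomb,
    vdw_6_12,
)
from saposim.geometry import RigidTransform, rotation_aligning

PROBE_RADIUS = 1.4  # water probe for accessible surface, Å
_SASA_POINTS = 300


class StructureParseError(ValueError):
    """Raised when a structure source cannot be parsed."""


class ParameterizationError(KeyError):
    """Raised when an atom cannot be resolved against the parameter table."""


class CombinatorialCapError(RuntimeError):
    """Raised when a torsion grid would exceed the enumeration cap."""


@dataclass(frozen=True)
class Atom:
    """One atom (or coarse bead) with its physicochemical parameters."""

    element: str
    position: np.ndarray
    partial_charge: float
    transfer_energy: float  # E_tr(i) = etr_per_area * S(i), kJ/mol
    accessible_surface: float  # S(i), Å²
    radius: float  # van der Waals, Å
    etr_per_area: float = 0.0  # kJ mol⁻¹ Å⁻², sign carries polarity

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.accessible_surface < 0:
            raise ValueError("accessible_surface must be non-negative")


@dataclass(frozen=True)
class ParameterizedMolecule:
    name: str
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int], ...] = ()
    rotatable_torsions: tuple[tuple[int, int, int, int], ...] = ()

    def __post_init__(self):
        n = len(self.atoms)
        if self.heavy_atom_count < 1:
            raise ValueError("molecule must contain at least one heavy atom")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) indexes outside {n} atoms")
        bondset = {frozenset(b) for b in self.bonds}
        for t in self.rotatable_torsions:
            if len(set(t)) != 4 or any(not (0 <= a < n) for a in t):
                raise ValueError(f"invalid torsion quadruple {t}")
            for a, b in zip(t, t[1:]):
                if frozenset((a, b)) not in bondset:
                    raise ValueError(f"torsion {t} is not a bonded path")

    @property
    def heavy_atom_count(self) -> int:
        return sum(a.is_heavy for a in self.atoms)

    # -- array views -----------------------------------------------------
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def surfaces(self) -> np.ndarray:
        return np.array([a.accessible_surface for a in self.atoms], dtype=float)

    def transfer_energies(self) -> np.ndarray:
        return np.array([a.transfer_energy for a in self.atoms], dtype=float)

    def etr_scales(self) -> np.ndarray:
        return np.array([a.etr_per_area for a in self.atoms], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def with_coordinates(self, coords: np.ndarray, recompute_sasa: bool = True) -> "ParameterizedMolecule":
        """Same topology and parameters at new coordinates.

        Accessible surfaces (and hence transfer energies) are conformation
        dependent and re-derived unless ``recompute_sasa`` is False.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate count must equal atom count")
        if recompute_sasa:
            s = accessible_surfaces(coords, self.radii())
        else:
            s = self.surfaces()
        atoms = tuple(
            replace(
                a,
                position=coords[i].copy(),
                accessible_surface=float(s[i]),
                transfer_energy=float(a.etr_per_area * s[i]),
            )
            for i, a in enumerate(self.atoms)
        )
        return replace(self, atoms=atoms)

    def transformed(self, t: RigidTransform) -> "ParameterizedMolecule":
        # rigid moves preserve the accessible surface
        return self.with_coordinates(t.apply(self.coordinates()), recompute_sasa=False)


@dataclass(frozen=True)
class Conformer:
    """One point of a torsion-grid scan of a parent molecule."""

    torsion_angles: tuple[float, ...]  # degrees, offsets applied per torsion
    coordinates: np.ndarray
    internal_energy: float  # kJ/mol, empirical intramolecular score


# ---------------------------------------------------------------------------
# accessible surface
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


_UNIT_SPHERE = _sphere_points(_SASA_POINTS)


def accessible_surfaces(
    coords: np.ndarray, radii: np.ndarray, probe: float = PROBE_RADIUS
) -> np.ndarray:
    """Per-atom solvent-accessible surface, Å² (Shrake–Rupley on a fixed point grid).

    Test points sit on each atom's solvent sphere (radius r_i + probe); a point
    is accessible if it lies outside every other atom's solvent sphere.  A lone
    atom returns the analytic 4π(r+probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    expanded = radii + probe
    out = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * _UNIT_SPHERE
        accessible = np.ones(len(pts), dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.mean()
        out[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return out


# ---------------------------------------------------------------------------
# parameter tables and structure input
# ---------------------------------------------------------------------------

def load_parameter_table(source=None) -> pd.DataFrame:
    """Parameter table indexed by element symbol.

    ``source`` may be a CSV path, a DataFrame, or None for the packaged
    element defaults.  Required columns: element, charge, etr_per_area, radius.
    """
    if source is None:
        text = resources.files("saposim.data").joinpath("element_params.csv").read_text()
        df = pd.read_csv(io.StringIO(text), comment="#")
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, comment="#")
    missing = {"element", "charge", "etr_per_area", "radius"} - set(df.columns)
    if missing:
        raise ParameterizationError(f"parameter table lacks columns {sorted(missing)}")
    df["element"] = df["element"].str.upper()
    return df.set_index("element")


def _resolve_params(element: str, params: pd.DataFrame) -> pd.Series:
    key = element.upper()
    if key not in params.index:
        raise ParameterizationError(
            f"no parameter row for element {element!r}; add it to the parameter table"
        )
    return params.loc[key]


def _infer_bonds(coords: np.ndarray, radii: np.ndarray, factor: float = 0.65) -> tuple:
    """Distance-based bond inference: d ≤ factor·(r_i + r_j)."""
    n = len(radii)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= factor * (radii[i] + radii[j]):
                bonds.append((i, j))
    return tuple(bonds)


def _build_molecule(
    name: str,
    elements: Sequence[str],
    coords: np.ndarray,
    params: pd.DataFrame,
    charges=None,
    etr_scales=None,
    radii=None,
    bonds=None,
    rotatable_torsions=(),
) -> ParameterizedMolecule:
    n = len(elements)
    coords = np.asarray(coords, dtype=float).reshape(n, 3)
    rows = [_resolve_params(e, params) for e in elements]
    q = np.array([rows[i]["charge"] if charges is None or charges[i] is None else charges[i] for i in range(n)], dtype=float)
    scale = np.array(
        [rows[i]["etr_per_area"] if etr_scales is None or etr_scales[i] is None else etr_scales[i] for i in range(n)],
        dtype=float,
    )
    r = np.array([rows[i]["radius"] if radii is None or radii[i] is None else radii[i] for i in range(n)], dtype=float)
    s = accessible_surfaces(coords, r)
    atoms = tuple(
        Atom(
            element=elements[i],
            position=coords[i].copy(),
            partial_charge=float(q[i]),
            transfer_energy=float(scale[i] * s[i]),
            accessible_surface=float(s[i]),
            radius=float(r[i]),
            etr_per_area=float(scale[i]),
        )
        for i in range(n)
    )
    if bonds is None:
        bonds = _infer_bonds(coords, r)
    return ParameterizedMolecule(
        name=name,
        atoms=atoms,
        bonds=tuple(tuple(b) for b in bonds),
        rotatable_torsions=tuple(tuple(t) for t in rotatable_torsions),
    )


def _read_pdb_atoms(path) -> tuple[list[str], np.ndarray]:
    """Elements and coordinates from ATOM/HETATM records (via biotite)."""
    import biotite.structure.io.pdb as pdbio

    try:
        pdb = pdbio.PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    elements = [e if e else n[0] for e, n in zip(arr.element, arr.atom_name)]
    return list(elements), np.asarray(arr.coord, dtype=float)


def read_structure(
    source,
    params=None,
    name: str | None = None,
    rotatable_torsions: Iterable[tuple[int, int, int, int]] = (),
) -> ParameterizedMolecule:
    """Read a molecule from PDB coordinates or a CSV atom table and parameterize it.

    The CSV dialect has one row per atom with columns ``name, element, x, y, z``
    and optional ``charge``, ``etr_per_area`` and ``radius`` overriding the
    per-element defaults of the parameter table.  Atom order is preserved.
    """
    params = load_parameter_table(params)
    path = Path(source)
    if path.suffix.lower() == ".pdb":
        elements, coords = _read_pdb_atoms(path)
        return _build_molecule(
            name or path.stem, elements, coords, params,
            rotatable_torsions=rotatable_torsions,
        )
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise StructureParseError(f"cannot parse atom table {path}: {exc}") from exc
    required = {"element", "x", "y", "z"}
    if not required <= set(df.columns):
        raise StructureParseError(
            f"atom table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)

    def _opt(col):
        if col not in df.columns:
            return None
        return [None if pd.isna(v) else float(v) for v in df[col]]

    return _build_molecule(
        name or path.stem,
        [str(e) for e in df["element"]],
        coords,
        params,
        charges=_opt("charge"),
        etr_scales=_opt("etr_per_area") if "etr_per_area" in df.columns else _opt("transfer_energy"),
        radii=_opt("radius"),
        rotatable_torsions=rotatable_torsions,
    )


def molecule_from_arrays(
    name: str,
    elements: Sequence[str],
    coords: np.ndarray,
    params=None,
    charges=None,
    etr_scales=None,
    radii=None,
    bonds=None,
    rotatable_torsions=(),
) -> ParameterizedMolecule:
    """Programmatic constructor used by the synthetic fixture builders."""
    return _build_molecule(
        name, elements, coords, load_parameter_table(params),
        charges=charges, etr_scales=etr_scales, radii=radii, bonds=bonds,
        rotatable_torsions=rotatable_torsions,
    )


def write_pdb(mol: ParameterizedMolecule, path) -> None:
    """Write coordinates as PDB ATOM records (via biotite)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    arr = struc.AtomArray(len(mol.atoms))
    arr.coord = mol.coordinates().astype(np.float32)
    for i, a in enumerate(mol.atoms):
        arr.element[i] = a.element.upper()
        arr.atom_name[i] = f"{a.element.upper()}{i + 1}"
        arr.res_name[i] = "MOL"
        arr.res_id[i] = 1
        arr.chain_id[i] = "A"
        arr.hetero[i] = True
    pdb = pdbio.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# conformer enumeration
# ---------------------------------------------------------------------------

def _bond_adjacency(mol: ParameterizedMolecule) -> list[set[int]]:
    adj = [set() for _ in mol.atoms]
    for i, j in mol.bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _graph_distances(adj: list[set[int]]) -> np.ndarray:
    """All-pairs bond-count distances (BFS; molecules are small)."""
    n = len(adj)
    dist = np.full((n, n), 10_000, dtype=int)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def _moving_side(adj: list[set[int]], j: int, k: int) -> list[int]:
    """Atoms on the k side of bond j-k (these rotate with the torsion)."""
    seen = {j, k}
    stack = [k]
    side = []
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                side.append(v)
                stack.append(v)
    return side


def _rotate_about_bond(coords, axis_a, axis_b, moving, angle_deg):
    axis = coords[axis_b] - coords[axis_a]
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = coords.copy()
    out[moving] = (coords[moving] - coords[axis_b]) @ R.T + coords[axis_b]
    return out


def internal_energy(
    mol: ParameterizedMolecule,
    coords: np.ndarray,
    torsion_offsets: Sequence[float] = (),
    cfg: ForceFieldConfig = INTRAMOLECULAR_FF,
    torsion_barrier: float = 0.5,
) -> float:
    """Empirical intramolecular score, kJ/mol.

    Nonbonded 6-12 + Coulomb (ε(r)=3r) over atom pairs separated by at least
    three bonds, an intramolecular hydrophobic contact reward for apolar pairs,
    and a threefold torsional term ½·V₀·(1+cos 3φ) per rotated torsion.
    """
    adj = _bond_adjacency(mol)
    gdist = _graph_distances(adj)
    n = len(mol.atoms)
    iu, ju = np.triu_indices(n, k=1)
    mask = gdist[iu, ju] >= 3
    iu, ju = iu[mask], ju[mask]
    if len(iu) == 0:
        nb = 0.0
    else:
        r = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        r = np.maximum(r, 1e-6)
        radii = mol.radii()
        sigma = radii[iu] + radii[ju]
        q = mol.charges()
        e_vdw = vdw_6_12(r, sigma, cfg.vdw_epsilon).sum()
        e_el = coulomb(r, q[iu] * q[ju], cfg.dielectric_slope).sum()
        scale = mol.etr_scales()
        surf = mol.surfaces()
        apolar = (scale[iu] < 0) & (scale[ju] < 0)
        s_etr = surf * np.abs(scale)
        from saposim.forcefield import hydrophobic_contact

        e_pho = float(
            hydrophobic_contact(r, sigma, apolar, s_etr[iu], s_etr[ju], cfg).sum()
        )
        nb = float(e_vdw + e_el) + e_pho
    e_tors = sum(
        0.5 * torsion_barrier * (1.0 + math.cos(math.radians(3.0 * a)))
        for a in torsion_offsets
    )
    return nb + e_tors


def has_clash(
    mol: ParameterizedMolecule, coords: np.ndarray, cfg: ForceFieldConfig = INTRAMOLECULAR_FF
) -> bool:
    """Steric clash check on nonbonded pairs (graph distance ≥ 3)."""
    adj = _bond_adjacency(mol)
    gdist = _graph_distances(adj)
    n = len(mol.atoms)
    iu, ju = np.triu_indices(n, k=1)
    mask = gdist[iu, ju] >= 3
    iu, ju = iu[mask], ju[mask]
    if len(iu) == 0:
        return False
    r = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    radii = mol.radii()
    return bool(np.any(r < cfg.clash_factor * (radii[iu] + radii[ju])))


def enumerate_conformations(
    mol: ParameterizedMolecule,
    step: float,
    max_conformers: int = 50_000,
    cfg: ForceFieldConfig = INTRAMOLECULAR_FF,
    return_rejected: bool = False,
):
    """Systematic torsion-grid scan, ascending by internal energy.

    Each rotatable torsion is swept through offsets 0, step, 2·step, … < 360°
    applied to the input geometry; grid points with steric clashes are
    discarded.  A molecule with no rotatable torsions yields its input
    geometry as the single conformer.
    """
    if step <= 0 or 360.0 % step != 0:
        raise ValueError("step must be a positive divisor of 360")
    torsions = mol.rotatable_torsions
    coords0 = mol.coordinates()
    if not torsions:
        conf = Conformer((), coords0, internal_energy(mol, coords0, cfg=cfg))
        return ([conf], 0) if return_rejected else [conf]
    n_per = int(round(360.0 / step))
    total = n_per ** len(torsions)
    if total > max_conformers:
        raise CombinatorialCapError(
            f"torsion grid of {total} points exceeds the cap of {max_conformers}; "
            f"raise max_conformers or coarsen the step"
        )
    adj = _bond_adjacency(mol)
    sides = [_moving_side(adj, t[1], t[2]) for t in torsions]
    angles = [i * step for i in range(n_per)]
    kept: list[Conformer] = []
    rejected = 0
    for combo in itertools.product(angles, repeat=len(torsions)):
        coords = coords0
        for (i0, j0, k0, _l0), side, ang in zip(torsions, sides, combo):
            if ang:
                coords = _rotate_about_bond(coords, j0, k0, side, ang)
        if has_clash(mol, coords, cfg):
            rejected += 1
            continue
        e = internal_energy(mol, coords, torsion_offsets=combo, cfg=cfg)
        kept.append(Conformer(tuple(float(a) for a in combo), coords, float(e)))
    kept.sort(key=lambda c: c.internal_energy)
    return (kept, rejected) if return_rejected else kept


def conformers_to_csv(conformers: Sequence[Conformer], path) -> None:
    rows = [
        {
            **{f"torsion_{k}_deg": a for k, a in enumerate(c.torsion_angles)},
            "internal_energy_kJ_mol": c.internal_energy,
        }
        for c in conformers
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interface orientation and interfacial area
# ---------------------------------------------------------------------------

def orient_at_interface(mol: ParameterizedMolecule) -> RigidTransform:
    """Rigid transform placing the molecule at the hydrophobic/hydrophilic interface.

    The axis from the hydrophobicity-weighted (S·|E_tr|, apolar atoms) centroid
    to the hydrophilicity-weighted (polar atoms) centroid is aligned with +z,
    hydrophobic centroid below, and the molecule is shifted so its
    amphiphilic balance point — the S·|etr|-weighted mean z over all atoms —
    sits at z = 0.  Molecules with no amphiphilic contrast get the identity
    with a warning.
    """
    coords = mol.coordinates()
    w = mol.surfaces() * np.abs(mol.etr_scales())
    scale = mol.etr_scales()
    w_pho = np.where(scale < 0, w, 0.0)
    w_phi = np.where(scale > 0, w, 0.0)
    if w_pho.sum() <= 0 or w_phi.sum() <= 0:
        warnings.warn(
            f"molecule {mol.name!r} has no amphiphilic contrast; orientation undefined",
            stacklevel=2,
        )
        return RigidTransform.identity()
    c_pho = (coords * w_pho[:, None]).sum(axis=0) / w_pho.sum()
    c_phi = (coords * w_phi[:, None]).sum(axis=0) / w_phi.sum()
    axis = c_phi - c_pho
    if np.linalg.norm(axis) < 1e-9:
        warnings.warn(
            f"molecule {mol.name!r} has coincident polar/apolar centroids",
            stacklevel=2,
        )
        return RigidTransform.identity()
    R = rotation_aligning(axis, np.array([0.0, 0.0, 1.0]))
    rotated = coords @ R.T
    z_bal = float((rotated[:, 2] * w).sum() / w.sum())
    xy = (rotated * w[:, None]).sum(axis=0) / w.sum()
    t = np.array([-xy[0], -xy[1], -z_bal])
    return RigidTransform(rotation=R, translation=t)


def interfacial_area(
    mol: ParameterizedMolecule,
    transform: RigidTransform | None = None,
    slab_half_width: float = 5.0,
    pixel: float = 0.05,
) -> float:
    """Area (Å²) of the union of atom disks projected onto the interface plane.

    Atoms whose center lies within ±slab_half_width of z = 0 (after applying
    ``transform``) are projected with their van der Waals radii; the union
    area is rasterized at ``pixel`` Å resolution.
    """
    coords = mol.coordinates() if transform is None else transform.apply(mol.coordinates())
    radii = mol.radii()
    in_slab = np.abs(coords[:, 2]) <= slab_half_width
    if not in_slab.any():
        warnings.warn("no atoms inside the interfacial slab; area is 0", stacklevel=2)
        return 0.0
    cx, cy, r = coords[in_slab, 0], coords[in_slab, 1], radii[in_slab]
    x0, x1 = (cx - r).min() - pixel, (cx + r).max() + pixel
    y0, y1 = (cy - r).min() - pixel, (cy + r).max() + pixel
    xs = np.arange(x0 + pixel / 2, x1, pixel)
    ys = np.arange(y0 + pixel / 2, y1, pixel)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros(X.shape, dtype=bool)
    for xi, yi, ri in zip(cx, cy, r):
        covered |= (X - xi) ** 2 + (Y - yi) ** 2 <= ri * ri
    return float(covered.sum()) * pixel * pixel
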