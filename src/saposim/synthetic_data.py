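"""Seeded generators for every input the pipeline consumes.

Four coarse fixture molecules reproduce the qualitative shapes that drive the
science: an elongated cholesterol-like sterol, an "L"-shaped Δ7-like sterol
(same atom multiset, different geometry — the two sterols share a chemical
formula), a conical amphiphilic saponin with a wide polar (sugar) base and an
apolar (aglycone) tail, and a two-tailed zwitterionic phospholipid.  The
geometries are idealized rods, bends and cones: the contracts they are built
for are orderings and signs, not chemical accuracy, and idealized fixtures
make those orderings a design guarantee rather than a force-field accident.

Interaction-matrix scenarios encode the docking-stage orderings directly
(saponin couples more strongly to the phospholipid than to either sterol, and
more strongly to cholesterol than to the Δ7 sterol; cholesterol self-couples
strongly, the bent Δ7 sterol weakly), so the lattice stage can be studied
without re-running the docking.  ITC and leakage generators produce noisy
traces from known parameters for recovery tests.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from saposim.bigmonolayer import MonolayerComposition
from saposim.hypermatrix import InteractionMatrix
from saposim.invitro import (
    DEFAULT_CELL_VOLUME_UL,
    DEFAULT_TEMPERATURE_K,
    TitrationSeries,
    model_heats,
)
from saposim.molecules import ParameterizedMolecule, molecule_from_arrays

FIXTURE_NAMES = ("dmpc_like", "cholesterol_like", "delta7_like", "frondoside_like")


def _rod(n: int, spacing: float = 1.5, z_top: float = 0.0) -> np.ndarray:
    """n beads going down the z axis from z_top."""
    return np.array([[0.0, 0.0, z_top - spacing * i] for i in range(n)])


def fixture_molecule(name: str) -> ParameterizedMolecule:
    """Hand-built coarse fixture molecule with parameterized beads.

    cholesterol_like
        One polar O head over an elongated straight rod of 8 apolar C beads.
    delta7_like
        The same 9-bead multiset with the lower half of the rod bent ~90°
        into a horizontal arm — the "L" shape of the Δ7 sterol.
    frondoside_like
        Conical amphiphile: 6-bead apolar tail under a wide two-ring polar
        base of 8 O beads (the bulky sugar moiety).
    dmpc_like
        Two 6-bead apolar tails under a zwitterionic head (P⁻/N⁺ plus an O).
    """
    if name == "cholesterol_like":
        coords = np.vstack([[[0.0, 0.0, 1.5]], _rod(12, z_top=0.0)])
        elements = ["O"] + ["C"] * 12
        return molecule_from_arrays(name, elements, coords)
    if name == "delta7_like":
        stem = _rod(6, z_top=0.0)  # z: 0 .. -7.5
        arm = np.array([[1.5 * (i + 1), 0.0, -7.5] for i in range(6)])
        coords = np.vstack([[[0.0, 0.0, 1.5]], stem, arm])
        elements = ["O"] + ["C"] * 12
        return molecule_from_arrays(name, elements, coords)
    if name == "frondoside_like":
        # the bulky sugar base spans a half-arc: one flank of the aglycone
        # tail stays accessible, as for a glycoside with a single sugar chain
        tail = _rod(10, z_top=-1.5)  # z: -1.5 .. -15
        arc1 = [
            [3.0 * math.cos(a), 3.0 * math.sin(a), 1.5]
            for a in np.linspace(0, math.pi, 6)
        ]
        arc2 = [
            [2.0 * math.cos(a), 2.0 * math.sin(a), 3.0]
            for a in (math.pi / 4, 3 * math.pi / 4)
        ]
        coords = np.vstack([arc1, arc2, tail])
        elements = ["O"] * 8 + ["C"] * 10
        return molecule_from_arrays(name, elements, coords)
    if name == "dmpc_like":
        head = np.array([[0.0, 0.0, 2.0], [0.0, 1.5, 3.0], [0.0, -1.5, 2.5]])
        tail_a = np.array([[1.2, 0.0, -1.5 * (i + 1)] for i in range(6)])
        tail_b = np.array([[-1.2, 0.0, -1.5 * (i + 1)] for i in range(6)])
        coords = np.vstack([head, tail_a, tail_b])
        elements = ["P", "N", "O"] + ["C"] * 12
        charges = [-0.3, 0.3, 0.0] + [0.0] * 12
        return molecule_from_arrays(name, elements, coords, charges=charges)
    raise KeyError(f"unknown fixture molecule {name!r}; choose from {FIXTURE_NAMES}")


def fixture_to_csv(name: str, path) -> None:
    """Write a fixture as the documented atom-table CSV dialect."""
    mol = fixture_molecule(name)
    rows = [
        {
            "name": f"{a.element}{i + 1}",
            "element": a.element,
            "x": a.position[0],
            "y": a.position[1],
            "z": a.position[2],
            "charge": a.partial_charge,
            "etr_per_area": a.etr_per_area,
            "radius": a.radius,
        }
        for i, a in enumerate(mol.atoms)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interaction-matrix scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("cholesterol_system", "delta7_system", "null_system")

_MATRIX_TYPES = ("DMPC", "CHOL", "DELTA7", "SAPONIN")

# per-heavy-atom energies (kJ/mol) encoding the docking-stage orderings:
# E(sap,DMPC) < E(sap,CHOL) < E(sap,DELTA7) < 0, strong CHOL-CHOL
# self-coupling (large round domains), weak DELTA7 self-coupling (scattered
# small clusters).
_SCENARIO_ENERGIES = {
    ("DMPC", "DMPC"): -1.0,
    ("DMPC", "CHOL"): -1.0,
    ("DMPC", "DELTA7"): -1.0,
    ("DMPC", "SAPONIN"): -2.0,
    ("CHOL", "CHOL"): -3.0,
    ("CHOL", "DELTA7"): -1.0,
    ("CHOL", "SAPONIN"): -1.5,
    ("DELTA7", "DELTA7"): -1.3,
    ("DELTA7", "SAPONIN"): -0.8,
    ("SAPONIN", "SAPONIN"): -1.0,
}


@dataclass(frozen=True)
class Scenario:
    """A named monolayer study condition: matrix targets plus composition."""

    name: str
    matrix_spec: dict[tuple[str, str], float]
    composition: MonolayerComposition
    seed: int = 0

    @property
    def sterol_type(self) -> str:
        for t in self.composition.fractions:
            if t in ("CHOL", "DELTA7"):
                return t
        raise ValueError(f"scenario {self.name!r} has no sterol type")


def make_scenario(name: str, seed: int = 0) -> Scenario:
    """Build one of the named scenarios (Methods composition 67/23/10)."""
    if name == "cholesterol_system":
        comp = {"DMPC": 0.67, "CHOL": 0.23, "SAPONIN": 0.10}
        spec = dict(_SCENARIO_ENERGIES)
    elif name == "delta7_system":
        comp = {"DMPC": 0.67, "DELTA7": 0.23, "SAPONIN": 0.10}
        spec = dict(_SCENARIO_ENERGIES)
    elif name == "null_system":
        comp = {"DMPC": 0.67, "CHOL": 0.23, "SAPONIN": 0.10}
        spec = {k: 0.0 for k in _SCENARIO_ENERGIES}
    else:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return Scenario(
        name=name, matrix_spec=spec, composition=MonolayerComposition(comp), seed=seed
    )


def synthetic_interaction_matrix(
    scenario: Scenario, jitter_sd: float = 0.0
) -> InteractionMatrix:
    """Symmetric matrix honoring the scenario's inequalities exactly.

    Optional seeded Gaussian jitter (small relative to the entry gaps) can be
    added for robustness studies; the default is the exact target values.
    """
    n = len(_MATRIX_TYPES)
    E = np.zeros((n, n))
    for (a, b), e in scenario.matrix_spec.items():
        ia, ib = _MATRIX_TYPES.index(a), _MATRIX_TYPES.index(b)
        E[ia, ib] = E[ib, ia] = e
    if jitter_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        noise = rng.normal(0.0, jitter_sd, size=(n, n))
        E = E + 0.5 * (noise + noise.T)
    return InteractionMatrix(types=_MATRIX_TYPES, energies=E)


# ---------------------------------------------------------------------------
# ITC and leakage traces
# ---------------------------------------------------------------------------

def simulate_itc_trace(
    K: float,
    dH: float,
    n_inj: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    injection_volume: float = 10.0,
    cell_concentration: float = 20.0,
    syringe_concentration: float = 5.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    cell_volume: float = DEFAULT_CELL_VOLUME_UL,
) -> TitrationSeries:
    """Synthetic titration from the partition model plus seeded Gaussian noise.

    Defaults mirror the experimental protocol: 10 µL injections of a 5 mM
    lipid suspension into ~20 µM saponin at 26 °C.  The generator parameters
    are recorded in ``series.metadata`` for recovery tests.
    """
    if n_inj < 1:
        raise ValueError("n_inj must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    base = TitrationSeries(
        injection_volumes=np.full(n_inj, float(injection_volume)),
        heats=np.zeros(n_inj),
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        temperature=temperature,
        cell_volume=cell_volume,
        metadata={"K": K, "dH": dH, "noise_sd": noise_sd, "seed": seed},
    )
    heats = model_heats(K, dH, base)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=n_inj)
    return TitrationSeries(
        injection_volumes=base.injection_volumes,
        heats=heats,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        temperature=temperature,
        cell_volume=cell_volume,
        metadata=base.metadata,
    )


def simulate_leakage_trace(
    level: float,
    F_contr: float = 10.0,
    F_tot: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float = 900.0,
    dt_s: float = 1.0,
    tau_s: float = 120.0,
) -> pd.DataFrame:
    """Saturating fluorescence trace plateauing at the given leakage level.

    F(t) = F_contr + (level/100)·(F_tot − F_contr)·(1 − e^(−t/τ)) over 900 s
    by default, plus seeded Gaussian noise.  Returns a DataFrame with columns
    ``time_s`` and ``F``.
    """
    if F_tot <= F_contr:
        raise ValueError("F_tot must exceed F_contr")
    if not -10.0 <= level <= 120.0:
        raise ValueError(f"leakage level {level} outside the sanity band [-10, 120] %")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    plateau = F_contr + level / 100.0 * (F_tot - F_contr)
    F = F_contr + (plateau - F_contr) * (1.0 - np.exp(-t / tau_s))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=len(t))
    return pd.DataFrame({"time_s": t, "F": F})


def plateau_fluorescence(trace: pd.DataFrame, window_s: float = 100.0) -> float:
    """Mean fluorescence over the trailing window (the leakage endpoint)."""
    t_end = trace["time_s"].max()
    return float(trace.loc[trace["time_s"] >= t_end - window_s, "F"].mean())
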