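"""Lattice monolayer minimized by Monte Carlo exchanges.

A monolayer is a square grid (default 200×200) with one molecule per cell.
The total energy is the sum of the pairwise interaction-matrix entries over
4-neighbor (von Neumann) pairs, with periodic boundaries by default.  The
composition is fixed: moves are Kawasaki exchanges — two cells of different
type swap occupants — accepted by the Metropolis rule, so type counts are
conserved exactly.  "Minimization" is simulated annealing: a geometric
temperature ladder from t_hot to t_cold followed by a zero-temperature quench.

Temperature here is a dimensionless Metropolis scale in the units of the
interaction matrix (per-heavy-atom kJ/mol): only the ratio ΔE/T matters for
phase behavior, so no physical k_B is introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from saposim.hypermatrix import InteractionMatrix


@dataclass(frozen=True)
class MonolayerComposition:
    """Molar fractions per molecule type; must sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.fractions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {vals.sum()}, expected 1")

    def counts(self, n_cells: int) -> dict[str, int]:
        """Largest-remainder rounding of fraction·n_cells to integer counts."""
        types = list(self.fractions)
        exact = np.array([self.fractions[t] * n_cells for t in types])
        base = np.floor(exact).astype(int)
        short = n_cells - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        for k in order[:short]:
            base[k] += 1
        out = dict(zip(types, (int(c) for c in base)))
        for t, c in out.items():
            if self.fractions[t] > 0 and c == 0:
                warnings.warn(f"type {t!r} has nonzero fraction but rounds to 0 cells", stacklevel=2)
        return out


#: composition of the saponin/sterol/phospholipid monolayers (Methods ratio).
DEFAULT_COMPOSITION = {"DMPC": 0.67, "STEROL": 0.23, "SAPONIN": 0.10}
#: alternative ratio quoted for the same systems in the results.
RESULTS_COMPOSITION = {"DMPC": 0.63, "STEROL": 0.27, "SAPONIN": 0.10}
#: saponin-free reference monolayer.
NO_SAPONIN_COMPOSITION = {"DMPC": 0.744, "STEROL": 0.256}


@dataclass
class LatticeState:
    """Square lattice of molecule-type codes with bookkept total energy."""

    grid: np.ndarray  # (side, side) int8 codes into `types`
    types: tuple[str, ...]
    rng_seed: int
    energy: float = 0.0
    periodic: bool = True

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    def type_counts(self) -> dict[str, int]:
        return {t: int((self.grid == i).sum()) for i, t in enumerate(self.types)}

    def copy(self) -> "LatticeState":
        return LatticeState(
            grid=self.grid.copy(),
            types=self.types,
            rng_seed=self.rng_seed,
            energy=self.energy,
            periodic=self.periodic,
        )


@dataclass(frozen=True)
class MCSchedule:
    """Annealing schedule for the Metropolis minimization."""

    n_steps: int
    t_hot: float = 1.5
    t_cold: float = 0.05
    n_stages: int = 12
    quench_fraction: float = 0.2  # trailing fraction of steps at T = 0
    seed: int = 0
    snapshot_every: int | None = None  # extra intermediate snapshots

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.t_hot < 0 or self.t_cold < 0:
            raise ValueError("temperature must be >= 0")

    def temperatures(self) -> np.ndarray:
        """Per-step temperature: geometric ladder then zero-T quench."""
        n_quench = int(self.n_steps * self.quench_fraction)
        n_anneal = self.n_steps - n_quench
        if n_anneal <= 0:
            return np.zeros(self.n_steps)
        stages = np.geomspace(max(self.t_hot, 1e-12), max(self.t_cold, 1e-12), self.n_stages)
        if self.t_hot == 0:
            stages = np.zeros(self.n_stages)
        per = np.repeat(stages, int(np.ceil(n_anneal / self.n_stages)))[:n_anneal]
        return np.concatenate([per, np.zeros(n_quench)])

    @staticmethod
    def fixed(n_steps: int, temperature: float, seed: int = 0) -> "MCSchedule":
        """Constant-temperature schedule (sampling rather than minimization)."""
        return MCSchedule(
            n_steps=n_steps,
            t_hot=temperature,
            t_cold=temperature,
            n_stages=1,
            quench_fraction=0.0,
            seed=seed,
        )


def init_lattice(
    comp: MonolayerComposition | dict,
    side: int = 200,
    seed: int = 0,
    M: InteractionMatrix | None = None,
    periodic: bool = True,
) -> LatticeState:
    """Seeded uniform random placement at the rounded composition counts."""
    if isinstance(comp, dict):
        comp = MonolayerComposition(comp)
    if side < 2:
        raise ValueError("side must be >= 2")
    counts = comp.counts(side * side)
    types = tuple(comp.fractions)
    codes = np.concatenate(
        [np.full(counts[t], i, dtype=np.int8) for i, t in enumerate(types)]
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(codes)
    state = LatticeState(
        grid=codes.reshape(side, side), types=types, rng_seed=seed, periodic=periodic
    )
    if M is not None:
        state.energy = lattice_energy(state, M)
    return state


def _neighbor_pairs(grid: np.ndarray, periodic: bool):
    """(type_a, type_b) code arrays over unordered 4-neighbor pairs."""
    if periodic:
        right = (grid, np.roll(grid, -1, axis=1))
        down = (grid, np.roll(grid, -1, axis=0))
    else:
        right = (grid[:, :-1], grid[:, 1:])
        down = (grid[:-1, :], grid[1:, :])
    a = np.concatenate([right[0].ravel(), down[0].ravel()])
    b = np.concatenate([right[1].ravel(), down[1].ravel()])
    return a, b


def lattice_energy(state: LatticeState, M: InteractionMatrix) -> float:
    """Total energy: Σ over unordered neighbor pairs of M(type_i, type_j)."""
    for t in state.types:
        if t not in M.types:
            raise KeyError(f"type {t!r} missing from the interaction matrix")
    lut = M.lookup_array(state.types)
    a, b = _neighbor_pairs(state.grid, state.periodic)
    return float(lut[a, b].sum())


def _local_energy(grid, lut, r, c, periodic, side):
    """Energy of the four edges incident to cell (r, c)."""
    t = grid[r, c]
    e = 0.0
    if periodic:
        e += lut[t, grid[(r - 1) % side, c]]
        e += lut[t, grid[(r + 1) % side, c]]
        e += lut[t, grid[r, (c - 1) % side]]
        e += lut[t, grid[r, (c + 1) % side]]
    else:
        if r > 0:
            e += lut[t, grid[r - 1, c]]
        if r < side - 1:
            e += lut[t, grid[r + 1, c]]
        if c > 0:
            e += lut[t, grid[r, c - 1]]
        if c < side - 1:
            e += lut[t, grid[r, c + 1]]
    return e


def mc_minimize(
    state: LatticeState,
    M: InteractionMatrix,
    sched: MCSchedule,
    n_snapshots: int = 2,
) -> list[LatticeState]:
    """Kawasaki-exchange Metropolis run; returns trajectory snapshots.

    Any two cells of different type may swap (global exchanges — fast
    equilibration of a conserved-composition mixture).  ΔE is computed from
    the eight edges incident to the two cells; the edge joining adjacent swap
    partners contributes equally before and after, so the local rule is exact.
    Fully seeded: identical state/schedule/seed give bit-identical grids.
    """
    out_state = state.copy()
    grid = out_state.grid
    side = out_state.side
    periodic = out_state.periodic
    lut = M.lookup_array(out_state.types)
    energy = lattice_energy(out_state, M)
    rng = np.random.default_rng(sched.seed)
    temps = sched.temperatures()
    n = sched.n_steps
    snaps: list[LatticeState] = []

    def take_snapshot():
        s = out_state.copy()
        s.energy = energy
        snaps.append(s)

    take_snapshot()
    if n == 0 or len(set(np.unique(grid))) < 2:
        return snaps
    snap_at = set(
        int(k * n / max(n_snapshots - 1, 1)) for k in range(1, max(n_snapshots, 2))
    )
    if sched.snapshot_every:
        snap_at |= set(range(sched.snapshot_every, n + 1, sched.snapshot_every))
    snap_at.add(n)
    batch = 65536
    done = 0
    while done < n:
        m = min(batch, n - done)
        sites = rng.integers(0, side, size=(m, 4))
        urand = rng.random(m)
        for k in range(m):
            r1, c1, r2, c2 = sites[k]
            t1 = grid[r1, c1]
            t2 = grid[r2, c2]
            if t1 == t2:
                done += 1
                if done in snap_at:
                    take_snapshot()
                continue
            e_before = _local_energy(grid, lut, r1, c1, periodic, side) + _local_energy(
                grid, lut, r2, c2, periodic, side
            )
            grid[r1, c1] = t2
            grid[r2, c2] = t1
            e_after = _local_energy(grid, lut, r1, c1, periodic, side) + _local_energy(
                grid, lut, r2, c2, periodic, side
            )
            dE = e_after - e_before
            T = temps[done]
            if dE <= 0 or (T > 0 and urand[k] < np.exp(-dE / T)):
                energy += dE
            else:
                grid[r1, c1] = t1
                grid[r2, c2] = t2
            done += 1
            if done in snap_at:
                take_snapshot()
    out_state.energy = energy
    return snaps


# ---------------------------------------------------------------------------
# rendering and text round trip
# ---------------------------------------------------------------------------

#: display palette for the monolayer figures: cholesterol yellow, DMPC teal,
#: saponin red, Δ7 sterol green.
DEFAULT_PALETTE = {
    "DMPC": (0, 128, 128),
    "STEROL": (255, 215, 0),
    "CHOL": (255, 215, 0),
    "DELTA7": (0, 160, 0),
    "SAPONIN": (220, 20, 20),
}


def render_lattice(state: LatticeState, palette: dict[str, tuple] | None = None):
    """One pixel per molecule; returns a PIL image in RGB."""
    from PIL import Image

    palette = palette or DEFAULT_PALETTE
    missing = [t for t in state.types if t not in palette]
    if missing:
        raise KeyError(f"palette lacks colors for types {missing}")
    lut = np.array([palette[t] for t in state.types], dtype=np.uint8)
    rgb = lut[state.grid]
    return Image.fromarray(rgb, mode="RGB")


def write_grid_text(state: LatticeState, path) -> None:
    """Plain-text grid: a header line of type names, then one row per lattice row."""
    with open(path, "w") as fh:
        fh.write("# types: " + ",".join(state.types) + "\n")
        fh.write(f"# seed: {state.rng_seed} periodic: {state.periodic}\n")
        for row in state.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_grid_text(path) -> LatticeState:
    types: tuple[str, ...] = ()
    seed = 0
    periodic = True
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# types:"):
                types = tuple(line.split(":", 1)[1].strip().split(","))
            elif line.startswith("# seed:"):
                parts = line[1:].split()
                seed = int(parts[1])
                periodic = parts[3] == "True"
            elif line:
                rows.append([int(v) for v in line.split()])
    grid = np.array(rows, dtype=np.int8)
    return LatticeState(grid=grid, types=types, rng_seed=seed, periodic=periodic)


def energy_trace(snapshots: list[LatticeState]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snapshot": range(len(snapshots)), "energy": [s.energy for s in snapshots]}
    )
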