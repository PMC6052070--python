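"""Sterol-domain quantification of lattice snapshots and the system comparison.

This reproduces a particle-analysis workflow on the rendered monolayer grids:
connected components of the target molecule type(s) are the "domains", their
areas are counted in cells (one cell = one molecule = one pixel), the mean
domain size is divided by the total area the target type occupies (so systems
of different composition are comparable), and the log of that relative mean
size is compared between systems with a Welch two-sample t test — large
variance differences between systems are expected, hence Welch rather than the
pooled-variance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from saposim.bigmonolayer import LatticeState


@dataclass(frozen=True)
class DomainLabeling:
    labels: np.ndarray  # per-cell domain id, 0 = background
    domain_sizes: np.ndarray  # cells per domain, label order

    @property
    def n_domains(self) -> int:
        return len(self.domain_sizes)


@dataclass(frozen=True)
class DomainStats:
    mean_size: float  # cells
    total_target_area: int  # cells
    n_domains: int

    @property
    def relative_mean_size(self) -> float:
        return self.mean_size / self.total_target_area

    @property
    def log_relative_mean_size(self) -> float:
        return float(np.log(self.relative_mean_size))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float  # Welch–Satterthwaite degrees of freedom
    p_value: float


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_domains(
    state: LatticeState | np.ndarray,
    target_types,
    connectivity: int = 8,
    boundary: str = "clipped",
) -> DomainLabeling:
    """Connected-component labeling of cells whose type is in ``target_types``.

    ``target_types`` are type names for a LatticeState or integer codes for a
    raw grid.  Connectivity 8 and clipped boundaries match an image-analysis
    particle count on the rendered grid; periodic boundaries are available for
    the simulation's native topology.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if boundary not in ("clipped", "periodic"):
        raise ValueError("boundary must be 'clipped' or 'periodic'")
    if isinstance(state, LatticeState):
        codes = [state.types.index(t) for t in target_types]
        grid = state.grid
    else:
        grid = np.asarray(state)
        codes = list(target_types)
    if not codes:
        raise ValueError("target_types must be non-empty")
    mask = np.isin(grid, codes)
    labels, n = ndimage.label(mask, structure=_STRUCTURE[connectivity])
    if boundary == "periodic" and n > 1:
        labels = _merge_periodic(labels, mask, connectivity)
        n = labels.max()
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:] if n else np.array([], dtype=int)
    return DomainLabeling(labels=labels, domain_sizes=sizes)


def _merge_periodic(labels: np.ndarray, mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Union labels across the wrap-around seams, then renumber densely."""
    n = labels.max()
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    rows, cols = labels.shape
    seams = [
        (labels[0, :], labels[-1, :]),
        (labels[:, 0], labels[:, -1]),
    ]
    if connectivity == 8:
        seams += [
            (labels[0, :], np.roll(labels[-1, :], 1)),
            (labels[0, :], np.roll(labels[-1, :], -1)),
            (labels[:, 0], np.roll(labels[:, -1], 1)),
            (labels[:, 0], np.roll(labels[:, -1], -1)),
        ]
    for a_line, b_line in seams:
        for a, b in zip(a_line, b_line):
            if a and b:
                union(int(a), int(b))
    roots = np.array([find(x) for x in range(n + 1)])
    dense = np.zeros(n + 1, dtype=labels.dtype)
    next_id = 0
    for x in range(1, n + 1):
        r = roots[x]
        if dense[r] == 0:
            next_id += 1
            dense[r] = next_id
    return dense[roots[labels]]


def domain_stats(lab: DomainLabeling) -> DomainStats:
    """Mean domain size, total target area, and the relative mean size."""
    if lab.n_domains == 0:
        raise ValueError("no domains: statistics undefined")
    total = int(lab.domain_sizes.sum())
    return DomainStats(
        mean_size=float(lab.domain_sizes.mean()),
        total_target_area=total,
        n_domains=lab.n_domains,
    )


def welch_test(group_a, group_b) -> TestResult:
    """Welch two-sample t test (unequal variances), two-sided.

    t = (x̄_A − x̄_B)/√(s²_A/n_A + s²_B/n_B) with Welch–Satterthwaite degrees
    of freedom; implemented closed-form (sample variances with n−1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult(statistic=0.0, df=float(na + nb - 2), p_value=1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)))


def compare_systems(
    run_a: list[DomainStats],
    run_b: list[DomainStats],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[TestResult, pd.DataFrame]:
    """Welch test on the log relative mean domain sizes of two replicate sets.

    Returns the test plus a tidy per-replicate table (system, replicate,
    mean_size, total_target_area, relative_mean_size, log_relative_mean_size).
    """
    if len(run_a) < 2 or len(run_b) < 2:
        raise ValueError("need at least two replicates per system")
    rows = []
    for label, run in ((label_a, run_a), (label_b, run_b)):
        for i, st in enumerate(run):
            rows.append(
                {
                    "system": label,
                    "replicate": i,
                    "n_domains": st.n_domains,
                    "mean_size": st.mean_size,
                    "total_target_area": st.total_target_area,
                    "relative_mean_size": st.relative_mean_size,
                    "log_relative_mean_size": st.log_relative_mean_size,
                }
            )
    table = pd.DataFrame(rows)
    res = welch_test(
        [s.log_relative_mean_size for s in run_a],
        [s.log_relative_mean_size for s in run_b],
    )
    return res, table
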