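"""Orchestration of the monolayer study: scenario → replicate runs → domain stats.

Thin glue reused by the analysis drivers, the tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from saposim.bigmonolayer import MCSchedule, init_lattice, mc_minimize
from saposim.domains import DomainStats, domain_stats, label_domains
from saposim.synthetic_data import Scenario, synthetic_interaction_matrix


@dataclass(frozen=True)
class MonolayerStudyConfig:
    """Lattice composition and Monte Carlo schedule of one replicate study."""

    scenario: str = "cholesterol_system"
    n_replicates: int = 5
    side: int = 100
    n_steps: int = 400_000
    base_seed: int = 1

    @staticmethod
    def from_yaml(path) -> "MonolayerStudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return MonolayerStudyConfig(**raw)


def run_scenario_replicates(
    scenario: Scenario,
    n_replicates: int = 5,
    side: int = 100,
    n_steps: int = 400_000,
    base_seed: int = 1,
    connectivity: int = 8,
    boundary: str = "clipped",
    return_states: bool = False,
):
    """Minimize ``n_replicates`` seeded lattices and return sterol-domain stats.

    Replicate k uses seeds derived from ``base_seed`` (initial placement and
    Monte Carlo stream are independent).  Domains are measured for the
    scenario's sterol type with image-analysis conventions (8-connectivity,
    clipped boundary) by default.
    """
    M = synthetic_interaction_matrix(scenario)
    stats: list[DomainStats] = []
    finals = []
    for k in range(n_replicates):
        seed = (base_seed * 1000 + k) % (2**31 - 1)
        state = init_lattice(scenario.composition, side=side, seed=seed, M=M)
        sched = MCSchedule(n_steps=n_steps, seed=seed + 500_000)
        final = mc_minimize(state, M, sched, n_snapshots=2)[-1]
        lab = label_domains(
            final, [scenario.sterol_type], connectivity=connectivity, boundary=boundary
        )
        stats.append(domain_stats(lab))
        finals.append(final)
    if return_states:
        return stats, finals
    return stats
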