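"""Empirical pairwise energy terms shared by the conformer scorer and the docking stage.

The field is deliberately coarse: a 6-12 van der Waals term between heavy
atoms, a Coulomb term with the distance-dependent dielectric ε(r) = 3r, and an
atomic hydrophobic contact term coupling the transfer energies of apolar atoms
in contact.  Constants live in :class:`ForceFieldConfig` and are meant to be
edited; the package's contracts are orderings and signs, not absolute
energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Coulomb constant e²/(4πε₀) in kJ·Å/mol.
COULOMB_KJ_A = 1389.35458


@dataclass(frozen=True)
class ForceFieldConfig:
    """Tunable constants of the empirical pairwise field.

    vdw_epsilon
        Well depth of the 6-12 term, kJ/mol; minimum sits at r = σ = r_i + r_j.
    dielectric_slope
        ε(r) = dielectric_slope · r (dimensionless per Å).
    hydrophobic_weight
        Scale w of the apolar-apolar contact term
        −w·(S_i·|etr_i| + S_j·|etr_j|), dimensionless.
    contact_margin
        Water-probe margin added to r_i + r_j for the contact criterion, Å.
    clash_factor
        Pairs closer than clash_factor · (r_i + r_j) are steric clashes.
    """

    vdw_epsilon: float = 0.4
    dielectric_slope: float = 3.0
    hydrophobic_weight: float = 0.40
    contact_margin: float = 1.4
    clash_factor: float = 0.7


DEFAULT_FF = ForceFieldConfig()

#: intramolecular scoring uses a gentler hydrophobic reward: within one small
#: molecule sterics dominate and a docking-strength contact term would drive
#: spurious hydrophobic collapse of short chains.
INTRAMOLECULAR_FF = ForceFieldConfig(hydrophobic_weight=0.05)


def vdw_6_12(r: np.ndarray, sigma: np.ndarray, epsilon: float) -> np.ndarray:
    """6-12 potential ε·((σ/r)¹² − 2(σ/r)⁶) with minimum −ε at r = σ."""
    x = (sigma / r) ** 6
    return epsilon * (x * x - 2.0 * x)


def coulomb(r: np.ndarray, qq: np.ndarray, slope: float) -> np.ndarray:
    """Coulomb energy under ε(r) = slope·r, i.e. k·q_iq_j/(slope·r²), kJ/mol."""
    return COULOMB_KJ_A * qq / (slope * r * r)


def contact_weight(r: np.ndarray, sum_radii: np.ndarray, cfg: ForceFieldConfig) -> np.ndarray:
    """Distance taper of the hydrophobic contact: min((σ/r)⁶, 1) inside reach, else 0.

    Tight packing at r ≈ σ = r_i + r_j earns the full contact reward while
    glancing contacts near the cutoff σ + contact_margin earn a fraction — the
    term thus favors shapes that pack flush against each other over shapes
    that only graze.
    """
    w = np.minimum((sum_radii / r) ** 6, 1.0)
    return np.where(r < sum_radii + cfg.contact_margin, w, 0.0)


def hydrophobic_contact(
    r: np.ndarray,
    sum_radii: np.ndarray,
    apolar_pair: np.ndarray,
    s_etr_i: np.ndarray,
    s_etr_j: np.ndarray,
    cfg: ForceFieldConfig,
) -> np.ndarray:
    """Tapered contact term −w·(S_i|etr_i| + S_j|etr_j|)·min((σ/r)⁶, 1) for apolar pairs.

    ``s_etr_i/j`` are the per-atom products S·|etr| (kJ/mol).  The term is zero
    outside the contact distance r_i + r_j + contact_margin and for any pair
    involving a polar atom.
    """
    taper = contact_weight(r, sum_radii, cfg)
    return np.where(apolar_pair, -cfg.hydrophobic_weight * (s_etr_i + s_etr_j) * taper, 0.0)
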