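"""Wet-lab arithmetic: calcein leakage, ITC blank subtraction and isotherm fitting.

Calcein leakage is normalized between a methanol (minimal) control and a
Triton X-100 (maximal) control:

    %Leakage = 100 · (F_t − F_contr) / (F_tot − F_contr)

ITC titrations inject lipid vesicles (syringe, mM) into a saponin solution
(cell, µM).  After subtracting the two blank titrations (lipid into buffer,
buffer into saponin), the per-injection heats are fitted with a lipid
partition model: the bound fraction of saponin is f = K·[L]/(1 + K·[L]), the
heat of injection i is ΔH·n_sap·(f_i − f_{i−1}), and [L] follows the injected
volume with dilution bookkeeping.  A one-site variant with the same
saturation algebra is available.  From the fitted K and ΔH the identities
ΔG = −R·T·ln(K·c°) (standard state c° = 1 M) and TΔS = ΔH − ΔG give the full
thermodynamic description.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_KJ = 8.314462618e-3  # gas constant, kJ/(mol·K)
STANDARD_STATE_M = 1.0  # c°, mol/L
DEFAULT_TEMPERATURE_K = 299.15  # 26 °C titration temperature
DEFAULT_CELL_VOLUME_UL = 200.0


@dataclass(frozen=True)
class LeakageRecord:
    F_t: float
    F_contr: float  # methanol (minimal) control
    F_tot: float  # Triton X-100 (maximal) control

    @property
    def percent_leakage(self) -> float:
        return leakage_percent(self.F_t, self.F_contr, self.F_tot)

    @property
    def out_of_range(self) -> bool:
        p = self.percent_leakage
        return p < 0.0 or p > 100.0


def leakage_percent(F_t: float, F_contr: float, F_tot: float) -> float:
    """Percentage of released calcein: 100·(F_t − F_contr)/(F_tot − F_contr).

    Values outside [0, 100] are possible for noisy inputs and returned as-is
    (use :class:`LeakageRecord.out_of_range` to flag them).
    """
    if F_tot == F_contr:
        raise ZeroDivisionError("F_tot equals F_contr: leakage normalization undefined")
    return 100.0 * (F_t - F_contr) / (F_tot - F_contr)


@dataclass(frozen=True)
class TitrationSeries:
    """One ITC titration: per-injection heats with the experiment geometry."""

    injection_volumes: np.ndarray  # µL, default 10 µL each
    heats: np.ndarray  # µJ per injection
    cell_concentration: float  # saponin in the cell, µM
    syringe_concentration: float  # lipid in the syringe, mM
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    cell_volume: float = DEFAULT_CELL_VOLUME_UL  # µL
    metadata: dict | None = None  # e.g. generator parameters of synthetic series

    def __post_init__(self):
        v = np.asarray(self.injection_volumes, dtype=float)
        h = np.asarray(self.heats, dtype=float)
        if v.shape != h.shape:
            raise ValueError("one heat per injection required")
        if (v <= 0).any():
            raise ValueError("injection volumes must be positive")
        object.__setattr__(self, "injection_volumes", v)
        object.__setattr__(self, "heats", h)

    @property
    def n_injections(self) -> int:
        return len(self.heats)

    def lipid_concentrations(self) -> np.ndarray:
        """Total lipid in the cell after each injection, mM (dilution included)."""
        v_cum = np.cumsum(self.injection_volumes)
        return self.syringe_concentration * v_cum / (self.cell_volume + v_cum)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "index": np.arange(1, self.n_injections + 1),
                "volume_uL": self.injection_volumes,
                "heat_uJ": self.heats,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic description of the binding at temperature T."""

    K: float  # binding constant, mM⁻¹
    dH: float  # kJ/mol
    dG: float  # kJ/mol
    TdS: float  # kJ/mol
    temperature: float  # K
    K_stderr: float = float("nan")
    dH_stderr: float = float("nan")
    residual_norm: float = float("nan")


class FitError(RuntimeError):
    """Isotherm fit did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def subtract_blanks(
    raw: TitrationSeries,
    blank_lipid_into_buffer: TitrationSeries,
    blank_buffer_into_saponin: TitrationSeries,
) -> TitrationSeries:
    """Corrected heats = raw − blank1 − blank2, element-wise."""
    for blank in (blank_lipid_into_buffer, blank_buffer_into_saponin):
        if blank.n_injections != raw.n_injections:
            raise ValueError("blank series must share the raw injection count")
        if not np.allclose(blank.injection_volumes, raw.injection_volumes):
            raise ValueError("blank series must share the raw injection volumes")
    corrected = raw.heats - blank_lipid_into_buffer.heats - blank_buffer_into_saponin.heats
    return replace(raw, heats=corrected)


def model_heats(
    K: float,
    dH: float,
    series: TitrationSeries,
) -> np.ndarray:
    """Per-injection heats (µJ) of the partition model at (K, ΔH).

    Bound saponin fraction after injection i: f_i = K·L_i/(1 + K·L_i) with L_i
    the diluted total lipid concentration (mM, so K is mM⁻¹); injection heat
    q_i = ΔH·n_sap·(f_i − f_{i−1}) with n_sap the fixed amount of saponin in
    the cell.
    """
    L = series.lipid_concentrations()
    f = K * L / (1.0 + K * L)
    df = np.diff(np.concatenate([[0.0], f]))
    # saponin amount: µM · µL = 1e-12 mol; dH kJ/mol → q in 1e-12 kJ = 1e-9 J
    n_sap_pmol = series.cell_concentration * series.cell_volume  # 1e-12 mol
    return dH * n_sap_pmol * df * 1e-3  # µJ


def fit_binding_isotherm(
    series: TitrationSeries,
    model: str = "partition",
    K0: float = 1.0,
    dH0: float | None = None,
) -> ThermoResult:
    """Least-squares fit of (K, ΔH) to the corrected injection heats.

    ``model`` 'partition' (default) treats the titrant as a partitioning lipid
    phase; 'one_site' uses the same saturation algebra and is provided for
    comparability — fitted constants are comparable only model-to-model.
    Returns the thermodynamic result with parameter standard errors (from the
    Jacobian) and the residual norm.
    """
    if model not in ("partition", "one_site"):
        raise ValueError(f"unknown model {model!r}")
    if series.n_injections < 6:
        raise ValueError("need at least 6 injections for an identifiable fit")
    heats = series.heats
    span = np.abs(heats).max()
    if span == 0 or np.abs(heats).std() / max(span, 1e-30) < 1e-12:
        import warnings

        warnings.warn("flat heat series: parameters weakly identifiable", stacklevel=2)
    if dH0 is None:
        n_sap_pmol = series.cell_concentration * series.cell_volume
        dH0 = float(heats.sum() / (n_sap_pmol * 1e-3)) or -1.0

    def residuals(theta):
        logK, dH = theta
        return model_heats(np.exp(logK), dH, series) - heats

    res = least_squares(residuals, x0=[np.log(K0), dH0], method="lm", max_nfev=10_000)
    if not res.success:
        raise FitError(f"isotherm fit did not converge: {res.message}", last_iterate=res.x)
    K = float(np.exp(res.x[0]))
    dH = float(res.x[1])
    # covariance from the Gauss-Newton approximation
    dof = max(series.n_injections - 2, 1)
    s2 = float(res.fun @ res.fun) / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        k_err = float(np.sqrt(cov[0, 0]) * K)  # delta method for K = exp(logK)
        dh_err = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        k_err = dh_err = float("nan")
    thermo = derive_thermodynamics(K, dH, series.temperature)
    return replace(
        thermo,
        K_stderr=k_err,
        dH_stderr=dh_err,
        residual_norm=float(np.linalg.norm(res.fun)),
    )


def derive_thermodynamics(K: float, dH: float, T: float = DEFAULT_TEMPERATURE_K) -> ThermoResult:
    """ΔG = −R·T·ln(K·c°) and TΔS = ΔH − ΔG (exact identities).

    K is in mM⁻¹ and is converted to M⁻¹ against the 1 M standard state, so
    K·c° = K · 1000.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    K_M = K * 1000.0  # mM⁻¹ → M⁻¹
    dG = -R_KJ * T * np.log(K_M * STANDARD_STATE_M)
    TdS = dH - dG
    return ThermoResult(K=float(K), dH=float(dH), dG=float(dG), TdS=float(TdS), temperature=float(T))


def read_titration_csv(
    path,
    cell_concentration: float,
    syringe_concentration: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    cell_volume: float = DEFAULT_CELL_VOLUME_UL,
) -> TitrationSeries:
    """Injections CSV with columns index, volume_uL, heat_uJ."""
    df = pd.read_csv(path, comment="#")
    return TitrationSeries(
        injection_volumes=df["volume_uL"].to_numpy(dtype=float),
        heats=df["heat_uJ"].to_numpy(dtype=float),
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        temperature=temperature,
        cell_volume=cell_volume,
    )
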