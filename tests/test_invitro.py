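"""Calcein leakage arithmetic, ITC corrections, isotherm fits, thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saposim.invitro import (
    R_KJ,
    LeakageRecord,
    TitrationSeries,
    derive_thermodynamics,
    fit_binding_isotherm,
    leakage_percent,
    subtract_blanks,
)
from saposim.synthetic_data import (
    plateau_fluorescence,
    simulate_itc_trace,
    simulate_leakage_trace,
)


# ---------------------------------------------------------------------------
# leakage
# ---------------------------------------------------------------------------

def test_leakage_controls():
    assert leakage_percent(100.0, 10.0, 100.0) == 100.0
    assert leakage_percent(10.0, 10.0, 100.0) == 0.0
    assert leakage_percent(55.0, 10.0, 100.0) == 50.0


def test_leakage_undefined_normalization():
    with pytest.raises(ZeroDivisionError):
        leakage_percent(5.0, 10.0, 10.0)


def test_out_of_range_flag():
    assert LeakageRecord(F_t=120.0, F_contr=10.0, F_tot=100.0).out_of_range
    assert not LeakageRecord(F_t=50.0, F_contr=10.0, F_tot=100.0).out_of_range


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    ft=st.floats(0, 200),
    a=st.floats(0.01, 100),
    b=st.floats(-50, 50),
)
def test_leakage_affine_invariance(ft, a, b):
    base = leakage_percent(ft, 10.0, 100.0)
    scaled = leakage_percent(a * ft + b, a * 10.0 + b, a * 100.0 + b)
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# blank subtraction
# ---------------------------------------------------------------------------

def _series(heats, vols=None):
    heats = np.asarray(heats, dtype=float)
    vols = np.full(len(heats), 10.0) if vols is None else np.asarray(vols)
    return TitrationSeries(
        injection_volumes=vols,
        heats=heats,
        cell_concentration=20.0,
        syringe_concentration=5.0,
    )


def test_zero_blanks_identity():
    raw = _series([-5.0, -3.0, -1.0])
    zero = _series([0.0, 0.0, 0.0])
    assert np.array_equal(subtract_blanks(raw, zero, zero).heats, raw.heats)


def test_blanks_annihilate_raw():
    raw = _series([-1.5, 2.0])
    b1 = _series([-1.0, 1.0])
    b2 = _series([-0.5, 1.0])
    assert np.allclose(subtract_blanks(raw, b1, b2).heats, 0.0)


def test_blank_subtraction_hand_arithmetic():
    raw = _series([-5.0, -3.0])
    b1 = _series([-1.0, -1.0])
    b2 = _series([0.5, 0.5])
    assert np.allclose(subtract_blanks(raw, b1, b2).heats, [-4.5, -2.5])


def test_mismatched_injection_count_rejected():
    with pytest.raises(ValueError):
        subtract_blanks(_series([1.0, 2.0]), _series([1.0]), _series([1.0, 2.0]))


# ---------------------------------------------------------------------------
# isotherm fitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("K_true,dH_true", [(0.1, -30.0), (1.0, -30.0), (10.0, 25.0)])
def test_noiseless_recovery_within_1_percent(K_true, dH_true):
    series = simulate_itc_trace(K_true, dH_true, n_inj=30)
    res = fit_binding_isotherm(series)
    assert res.K == pytest.approx(K_true, rel=0.01)
    assert res.dH == pytest.approx(dH_true, rel=0.01)


def test_heat_scaling_doubles_dH_leaves_K():
    series = simulate_itc_trace(1.5, -30.0, n_inj=30)
    doubled = TitrationSeries(
        injection_volumes=series.injection_volumes,
        heats=series.heats * 2.0,
        cell_concentration=series.cell_concentration,
        syringe_concentration=series.syringe_concentration,
        temperature=series.temperature,
        cell_volume=series.cell_volume,
    )
    r1 = fit_binding_isotherm(series)
    r2 = fit_binding_isotherm(doubled)
    assert r2.dH == pytest.approx(2.0 * r1.dH, rel=1e-6)
    assert r2.K == pytest.approx(r1.K, rel=1e-6)


def test_noisy_recovery_within_15_percent():
    clean = simulate_itc_trace(1.5, -30.0, n_inj=30)
    noise_sd = 0.05 * np.abs(clean.heats).max()
    noisy = simulate_itc_trace(1.5, -30.0, n_inj=30, noise_sd=noise_sd, seed=11)
    res = fit_binding_isotherm(noisy)
    assert res.K == pytest.approx(1.5, rel=0.15)
    assert res.dH == pytest.approx(-30.0, rel=0.15)


def test_too_few_injections_rejected():
    with pytest.raises(ValueError):
        fit_binding_isotherm(simulate_itc_trace(1.0, -30.0, n_inj=4))


# ---------------------------------------------------------------------------
# thermodynamic identities
# ---------------------------------------------------------------------------

def test_unit_K_c0_gives_zero_dG():
    res = derive_thermodynamics(K=1e-3, dH=-12.0, T=299.15)  # K·c° = 1
    assert res.dG == pytest.approx(0.0, abs=1e-12)
    assert res.TdS == pytest.approx(-12.0, rel=1e-12)


def test_fish_like_binding_constant_thermodynamics():
    # K = 469.6 mM⁻¹ at 26 °C: dG = -R·T·ln(4.696e5) with c° = 1 M
    res = derive_thermodynamics(K=469.6, dH=-5.0, T=299.15)
    expected_dG = -R_KJ * 299.15 * np.log(4.696e5)
    assert res.dG == pytest.approx(expected_dG, rel=1e-12)
    assert res.dG < 0
    assert res.dG == pytest.approx(res.dH - res.TdS, rel=1e-12)
    assert abs(res.TdS) > abs(res.dH)  # entropy-dominated at this K and dH


def test_doubling_K_shifts_dG_by_RTln2():
    r1 = derive_thermodynamics(K=2.0, dH=0.0, T=300.0)
    r2 = derive_thermodynamics(K=4.0, dH=0.0, T=300.0)
    assert r2.dG - r1.dG == pytest.approx(-R_KJ * 300.0 * np.log(2.0), rel=1e-12)


def test_nonpositive_K_rejected():
    with pytest.raises(ValueError):
        derive_thermodynamics(K=0.0, dH=1.0)


# ---------------------------------------------------------------------------
# synthetic trace generators
# ---------------------------------------------------------------------------

def test_zero_enthalpy_gives_zero_heats():
    s = simulate_itc_trace(K=2.0, dH=0.0, n_inj=10)
    assert np.allclose(s.heats, 0.0)


def test_heats_saturate_toward_zero():
    s = simulate_itc_trace(K=5.0, dH=-30.0, n_inj=30)
    assert abs(s.heats[-1]) < 0.05 * abs(s.heats[0])


def test_generators_are_pure_functions_of_seed():
    a = simulate_itc_trace(1.0, -30.0, n_inj=10, noise_sd=1.0, seed=3)
    b = simulate_itc_trace(1.0, -30.0, n_inj=10, noise_sd=1.0, seed=3)
    assert np.array_equal(a.heats, b.heats)
    ta = simulate_leakage_trace(40.0, noise_sd=0.3, seed=3)
    tb = simulate_leakage_trace(40.0, noise_sd=0.3, seed=3)
    assert np.array_equal(ta["F"], tb["F"])


def test_leakage_trace_plateaus_at_level():
    for level in (0.0, 100.0, 42.0):
        tr = simulate_leakage_trace(level, F_contr=10.0, F_tot=100.0)
        rec = leakage_percent(plateau_fluorescence(tr), 10.0, 100.0)
        assert rec == pytest.approx(level, abs=0.2)


def test_leakage_level_sanity_band():
    with pytest.raises(ValueError):
        simulate_leakage_trace(150.0)
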