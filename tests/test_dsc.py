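"""Two-state DSC model, baseline handling and thermodynamic observables."""

import warnings

import numpy as np
import pytest

from metallobind.dsc import (
    R_KJ,
    Thermogram,
    TwoStateParams,
    correct_native_loss,
    entropy_at_td,
    find_td,
    fit_two_state,
    integrate_enthalpy,
    subtract_baseline,
    two_state_cp,
)
from metallobind.simulate import simulate_dsc

TD = 350.0
DH = 450.0


def test_thermogram_validation():
    with pytest.raises(ValueError, match="increasing"):
        Thermogram(np.array([300.0, 300.0]), np.zeros(2))
    with pytest.raises(ValueError):
        Thermogram(np.array([300.0, 301.0]), np.zeros(3))


def test_two_state_cp_value_at_midpoint():
    """At T = T_d half the protein is unfolded and Cp_exc = dH^2/(4 R T_d^2)."""
    expected = DH**2 / (4.0 * R_KJ * TD**2)
    assert two_state_cp(TD, DH, TD) == pytest.approx(expected, rel=1e-12)


def test_two_state_cp_peak_height_closed_form(clean_thermogram):
    expected = DH**2 / (4.0 * R_KJ * TD**2)
    assert float(np.max(clean_thermogram.cp_exc)) == \
        pytest.approx(expected, rel=1e-3)


def test_two_state_cp_no_overflow_far_from_transition():
    cp = two_state_cp(np.array([280.0, 420.0]), 5000.0, TD)
    assert np.all(np.isfinite(cp))
    assert np.all(cp >= 0.0)


def test_integrated_area_equals_enthalpy(clean_thermogram):
    assert integrate_enthalpy(clean_thermogram) == pytest.approx(DH, rel=1e-3)


def test_find_td_exact_peak_location(clean_thermogram):
    """With dCp = 0 the Cp_exc maximum sits slightly below T_d; expanding
    dCp_exc/dT = 0 to first order gives the offset -4 R^2 T_d^3 / dH^2."""
    offset = -4.0 * R_KJ**2 * TD**3 / DH**2
    assert find_td(clean_thermogram) == pytest.approx(TD + offset, abs=5e-3)


def test_find_td_warns_on_shouldered_thermogram():
    t = simulate_dsc(populations=[(0.5, 352.0, 450.0), (0.5, 344.0, 450.0)])
    with pytest.warns(UserWarning, match="shouldered"):
        find_td(t)


def test_fit_two_state_recovers_clean_parameters(clean_thermogram):
    p = fit_two_state(clean_thermogram)
    assert p.status == "OK"
    assert p.t_d_k == pytest.approx(TD, abs=1e-3)
    assert p.dh_vh == pytest.approx(DH, rel=1e-4)
    assert p.dh_cal == pytest.approx(DH, rel=1e-3)
    assert p.cooperativity_ratio == pytest.approx(1.0, rel=2e-3)
    assert p.rms_residual < 1e-6 * p.peak_height


def test_fit_two_state_recovers_noisy_parameters():
    t = simulate_dsc(t_d_k=TD, dh=DH, sigma_frac=0.01, seed=3)
    p = fit_two_state(t)
    assert p.status == "OK"
    assert p.t_d_k == pytest.approx(TD, abs=0.1)
    assert p.dh_vh == pytest.approx(DH, rel=0.02)


def test_fit_two_state_fails_on_two_population_mixture():
    """An equimolar mixture of species unfolding 6 K apart is not two-state:
    the single-transition fit leaves > 5% of peak height in the residuals."""
    t = simulate_dsc(populations=[(0.5, 348.0, DH), (0.5, 342.0, DH)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fit_two_state(t)
    assert p.status == "FAILED"
    assert any("RMS residual" in f for f in p.flags)
    assert p.rms_residual > 0.05 * p.peak_height


def test_entropy_at_midpoint():
    p = TwoStateParams(t_d_k=TD, dh_cal=DH, dh_vh=DH * 1.02)
    assert entropy_at_td(p) == pytest.approx(DH / TD)
    assert entropy_at_td(p, use_vh=True) == pytest.approx(DH * 1.02 / TD)


def test_baseline_roundtrip_on_ramped_thermogram():
    """Adding a sloped linear baseline plus offset and subtracting the
    progress baseline recovers the endotherm and its area."""
    clean = simulate_dsc(t_d_k=340.0, dh=DH, sigma_frac=0.0)
    t = clean.temperature_k
    ramp = 0.5 + 0.02 * (t - t[0])  # kJ/mol/K instrumental drift
    raw = Thermogram(t, clean.cp_exc + ramp)
    corrected = subtract_baseline(raw)
    peak = float(np.max(clean.cp_exc))
    rms = float(np.sqrt(np.mean((corrected.cp_exc - clean.cp_exc) ** 2)))
    assert rms < 0.005 * peak
    assert integrate_enthalpy(corrected) == pytest.approx(DH, rel=0.01)


def test_baseline_windows_must_avoid_the_peak():
    clean = simulate_dsc(t_d_k=340.0, dh=DH)
    t = clean.temperature_k
    with pytest.raises(ValueError, match="overlap"):
        subtract_baseline(clean, pre_window=(t[0], 345.0))
    with pytest.raises(ValueError, match=">= 5"):
        subtract_baseline(clean, pre_window=(t[0], t[0] + 0.1))


def test_baseline_of_flat_signal_is_flat():
    t = np.arange(293.15, 368.15, 0.1)
    flat = Thermogram(t, np.full_like(t, 1.25))
    out = subtract_baseline(flat)
    assert np.allclose(out.cp_exc, 0.0, atol=1e-9)


def test_correct_native_loss_composes_multiplicatively():
    t = simulate_dsc(t_d_k=340.0, dh=DH)
    out = correct_native_loss(t, (0.12, 0.09))
    factor = 1.0 / (0.88 * 0.91)
    assert out.cp_exc == pytest.approx(t.cp_exc * factor)
    assert integrate_enthalpy(out) == pytest.approx(
        integrate_enthalpy(t) * factor)
    with pytest.raises(ValueError):
        correct_native_loss(t, 1.0)
    with pytest.raises(ValueError):
        correct_native_loss(t, -0.1)
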