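"""Binding-isotherm construction and the linearized/nonlinear estimators."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from metallobind.titration import (
    BindingIsotherm,
    Spectrum,
    TitrationPoint,
    TitrationSeries,
    build_isotherm,
    concentration_from_a280,
    correct_dilution,
    diff_spectra,
    fit_eq2_iterative,
    fit_eq3_scatchard,
    nls_oracle_fit,
    runs_test,
    solve_equilibrium,
)
from metallobind.simulate import simulate_titration


# ---------------------------------------------------------------------------
# containers


def test_spectrum_validation_and_interpolation():
    wl = np.array([300.0, 310.0, 320.0])
    s = Spectrum(wl, np.array([0.0, 1.0, 0.0]))
    assert s.at(305.0) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="outside"):
        s.at(299.0)
    with pytest.raises(ValueError, match="increasing"):
        Spectrum(np.array([300.0, 300.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        Spectrum(wl, np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        Spectrum(wl, np.zeros(3), path_cm=0.0)


def test_series_requires_protein_free_point_zero():
    s = Spectrum(np.array([300.0, 400.0]), np.zeros(2))
    good = TitrationPoint(c_ptl=1e-4, c_protein=0.0, spectrum=s)
    bad = TitrationPoint(c_ptl=1e-4, c_protein=1e-5, spectrum=s)
    TitrationSeries(points=[good, bad])
    with pytest.raises(ValueError, match="protein-free"):
        TitrationSeries(points=[bad, good])
    with pytest.raises(ValueError, match="non-decreasing"):
        TitrationSeries(points=[
            good,
            TitrationPoint(c_ptl=1e-4, c_protein=2e-5, spectrum=s),
            TitrationPoint(c_ptl=1e-4, c_protein=1e-5, spectrum=s),
        ])


# ---------------------------------------------------------------------------
# elementary operations


def test_correct_dilution_rescales_by_volume_ratio():
    s = Spectrum(np.array([300.0, 400.0]), np.array([0.5, 1.0]))
    out = correct_dilution(s, v0=1.0e-3, v_added=1.0e-4)
    assert out.absorbance == pytest.approx(1.1 * s.absorbance)
    with pytest.raises(ValueError):
        correct_dilution(s, v0=0.0, v_added=1e-4)


def test_concentration_from_a280_beer_lambert():
    # lysozyme epsilon 38,940; ribonuclease A epsilon 8,640 (1/M/cm)
    assert concentration_from_a280(0.3894, 38940.0) == pytest.approx(1.0e-5)
    assert concentration_from_a280(0.0864, 8640.0, path_cm=1.0) == \
        pytest.approx(1.0e-5)
    with pytest.raises(ValueError):
        concentration_from_a280(0.5, 0.0)


def test_solve_equilibrium_limits():
    # K -> 0: nothing bound; huge K: stoichiometric limit
    assert solve_equilibrium(1e-4, 1e-4, 0.0) == 0.0
    assert solve_equilibrium(1e-4, 2e-4, 1e12) == pytest.approx(1e-4, rel=1e-6)
    assert solve_equilibrium(2e-4, 1e-4, 1e12) == pytest.approx(1e-4, rel=1e-6)
    # n = 0.5 halves the available sites
    assert solve_equilibrium(2e-4, 1e-4, 1e12, n=0.5) == \
        pytest.approx(0.5e-4, rel=1e-6)


def test_solve_equilibrium_vectorized():
    c_p = np.array([0.0, 1e-5, 1e-4])
    x = solve_equilibrium(1.3e-4, c_p, 1e4)
    assert x.shape == (3,)
    assert x[0] == 0.0
    assert np.all(np.diff(x) > 0)


def _equilibrium_oracle(c_ptl, c_prot, k, n):
    """Independent root-bracketing solution of the mass-action condition."""
    sites = n * c_prot
    hi = min(c_ptl, sites)
    if hi == 0 or k == 0:
        return 0.0

    def f(x):
        return k * (c_ptl - x) * (sites - x) - x

    return brentq(f, 0.0, hi, xtol=1e-18, rtol=1e-14)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    c_ptl=st.floats(1e-6, 1e-2),
    c_prot=st.floats(0.0, 1e-2),
    k=st.floats(1.0, 1e7),
    n=st.sampled_from([0.5, 1.0, 2.0]),
)
def test_solve_equilibrium_against_bracketing_oracle(c_ptl, c_prot, k, n):
    x = solve_equilibrium(c_ptl, c_prot, k, n)
    assert 0.0 <= x <= min(c_ptl, n * c_prot) + 1e-18
    x_ref = _equilibrium_oracle(c_ptl, c_prot, k, n)
    assert x == pytest.approx(x_ref, rel=1e-9, abs=1e-15)


def test_build_isotherm_clean(clean_isotherm, clean_series):
    iso = clean_isotherm
    assert iso.delta_a[0] == 0.0
    assert iso.eps_ptl == pytest.approx(1.0e4, rel=1e-12)
    # dA = delta_eps * x exactly on model data
    x = solve_equilibrium(iso.c_ptl, iso.c_protein, 1.0e4)
    assert iso.delta_a == pytest.approx(-5000.0 * x, rel=1e-9)


def test_build_isotherm_default_wavelength(clean_series):
    iso = build_isotherm(clean_series)
    assert 300.0 <= iso.lambda_star_nm <= 500.0
    # the default analysis wavelength maximizes the final |dA|
    alt = build_isotherm(clean_series, lambda_star=iso.lambda_star_nm + 40.0)
    assert abs(iso.delta_a[-1]) >= abs(alt.delta_a[-1])


def test_build_isotherm_needs_enough_points():
    s = Spectrum(np.array([300.0, 400.0]), np.array([0.1, 0.1]))
    pts = [TitrationPoint(c_ptl=1e-4, c_protein=0.0, spectrum=s),
           TitrationPoint(c_ptl=1e-4, c_protein=1e-5, spectrum=s)]
    with pytest.raises(ValueError, match=">= 4"):
        build_isotherm(TitrationSeries(points=pts), lambda_star=350.0)


def test_diff_spectra_reports_largest_change():
    wl = np.arange(300.0, 401.0, 1.0)
    s1 = Spectrum(wl, np.zeros_like(wl))
    s2 = Spectrum(wl, np.exp(-0.5 * ((wl - 350.0) / 10.0) ** 2))
    _, diff, dmax, lam = diff_spectra(s1, s2)
    assert dmax == pytest.approx(1.0)
    assert lam == 350.0


def test_runs_test_flags_grouped_residuals():
    grouped = np.array([1, 1, 1, 1, 1, 1, -1, -1, -1, -1, -1, -1], dtype=float)
    alternating = np.array([1, -1] * 6, dtype=float)
    assert runs_test(grouped) < 0.05
    assert runs_test(alternating) < 0.05  # too many runs is also non-random
    mixed = np.array([1, 1, -1, 1, -1, -1, 1, -1, 1, 1, -1, -1], dtype=float)
    assert runs_test(mixed) > 0.05


# ---------------------------------------------------------------------------
# estimators


def test_eq2_exact_on_clean_data(clean_isotherm):
    fit = fit_eq2_iterative(clean_isotherm)
    assert fit.converged
    assert fit.k == pytest.approx(1.0e4, rel=1e-6)
    assert fit.delta_eps == pytest.approx(-5000.0, rel=1e-6)
    assert fit.n_iter <= 20
    assert fit.k_reliable
    assert fit.eps_bound == pytest.approx(5000.0, rel=1e-6)


def test_eq2_iteration_trace_converges_to_fixed_point(clean_isotherm):
    """The recorded d_eps trace ends at the reported fixed point with its
    final update below the convergence tolerance."""
    fit = fit_eq2_iterative(clean_isotherm)
    trace = np.asarray(fit.delta_eps_trace, dtype=float)
    assert trace.size >= 3
    assert trace[-1] == fit.delta_eps
    assert abs(trace[-1] - trace[-2]) <= 1e-6 * abs(trace[-1])
    # the final updates are far smaller than the initial ones
    assert abs(trace[-1] - trace[-2]) < 1e-4 * abs(trace[1] - trace[0])


@pytest.mark.parametrize("k_true", [1.0e2, 1.0e3, 1.0e4, 1.0e5])
def test_eq2_matches_nls_oracle_across_affinities(k_true):
    series = simulate_titration(k=k_true, delta_eps=-5000.0, sigma_a=0.0)
    iso = build_isotherm(series, lambda_star=378.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        it = fit_eq2_iterative(iso)
        nls = nls_oracle_fit(iso)
    assert it.n_iter <= 20
    assert abs(it.k - nls.k) / nls.k < 1e-3
    assert it.k == pytest.approx(k_true, rel=1e-3)


def test_eq2_zero_da_points_dropped_with_warning(clean_isotherm):
    iso = clean_isotherm
    da = iso.delta_a.copy()
    da[3] = 0.0
    broken = BindingIsotherm(iso.c_ptl, iso.c_protein, da,
                             iso.lambda_star_nm, iso.eps_ptl)
    with pytest.warns(UserWarning, match="dA = 0"):
        fit = fit_eq2_iterative(broken)
    assert fit.k == pytest.approx(1.0e4, rel=1e-4)


def test_eq2_noisy_single_seed_reasonable():
    series = simulate_titration(k=1.0e4, delta_eps=-5000.0, sigma_a=0.002,
                                seed=7)
    iso = build_isotherm(series, lambda_star=378.0)
    fit = fit_eq2_iterative(iso)
    assert fit.converged
    assert np.isfinite(fit.k_stderr) and fit.k_stderr > 0
    assert 0.2e4 < fit.k < 5e4


def test_eq3_exact_on_clean_half_site_data():
    series = simulate_titration(k=3.0e4, n=0.5, delta_eps=-5000.0, sigma_a=0.0)
    iso = build_isotherm(series, lambda_star=378.0)
    sc = fit_eq3_scatchard(iso, delta_eps=-5000.0)
    assert sc.n_sites == pytest.approx(0.5, rel=1e-6)
    assert sc.k == pytest.approx(3.0e4, rel=1e-6)


def test_eq3_rejects_wrong_sign_delta_eps(clean_isotherm):
    with pytest.raises(ValueError, match="sign"):
        fit_eq3_scatchard(clean_isotherm, delta_eps=+5000.0)
    with pytest.raises(ValueError):
        fit_eq3_scatchard(clean_isotherm, delta_eps=0.0)


def test_nls_oracle_exact_on_clean_data(clean_isotherm):
    fit = nls_oracle_fit(clean_isotherm)
    assert fit.converged
    assert fit.k == pytest.approx(1.0e4, rel=1e-6)
    assert fit.delta_eps == pytest.approx(-5000.0, rel=1e-6)
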