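"""Adduct mass bookkeeping, assignment and envelope deconvolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metallobind.adducts import (
    AdductAssignment,
    FragmentSpec,
    NeutralPeakList,
    assign_adducts,
    deconvolve_envelope,
    mz_from_mass,
    predict_adduct_mass,
)
from metallobind.formula import HYDROGEN_MASS, PROTON_MASS, average_mass

PT_TERPY = FragmentSpec(label="Pt(terpy-Ph)", formula="PtC21H15N3", charge=2)

RNASE_A = 13682.0
HEWL = 14304.0


def test_fragment_mass_shift_is_mass_minus_charge_hydrogens():
    expected = average_mass("PtC21H15N3") - 2 * HYDROGEN_MASS
    assert PT_TERPY.mass_shift == pytest.approx(expected, abs=1e-9)
    assert PT_TERPY.mass_shift == pytest.approx(502.440, abs=0.01)


def test_fragment_charge_configurable():
    q1 = FragmentSpec(label="q1", formula="PtC21H15N3", charge=1)
    q0 = FragmentSpec(label="q0", formula="PtC21H15N3", charge=0)
    assert q1.mass_shift == pytest.approx(PT_TERPY.mass_shift + HYDROGEN_MASS)
    assert q0.mass_shift == pytest.approx(average_mass("PtC21H15N3"))
    with pytest.raises(ValueError):
        FragmentSpec(label="bad", formula="PtC21H15N3", charge=3)


@pytest.mark.parametrize(
    ("m0", "k", "expected"),
    [
        (RNASE_A, 0, RNASE_A),
        (RNASE_A, 1, 14184.0),   # mono-adduct on ribonuclease A
        (RNASE_A, 2, 14687.0),   # bis-adduct
        (HEWL, 1, 14806.0),      # lysozyme mono-adduct
    ],
)
def test_predict_adduct_mass_rounded(m0, k, expected):
    assert round(predict_adduct_mass(m0, PT_TERPY, k)) == expected


def test_predict_adduct_mass_rejects_bad_inputs():
    with pytest.raises(ValueError):
        predict_adduct_mass(0.0, PT_TERPY, 1)
    with pytest.raises(ValueError):
        predict_adduct_mass(RNASE_A, PT_TERPY, -1)


def test_assignment_of_observed_mass_roster():
    """The five observed neutral masses of the platinated ribonuclease sample
    map onto P, P+H3PO4/H2SO4, P+1 fragment, P+1 fragment+anion, P+2."""
    observed = np.array([13682.0, 13780.0, 14184.0, 14283.0, 14686.0])
    peaks = NeutralPeakList(observed, np.ones(5), tolerance_da=1.5)
    out = assign_adducts(peaks, RNASE_A, [PT_TERPY], k_max=2)
    assert [a.k for a in out] == [0, 0, 1, 1, 2]
    # bare protein and both platinated peaks are unambiguous protein species
    assert out[0].small_adduct is None
    assert out[2].small_adduct is None
    # the +98 peaks carry the isobaric sulphate/phosphate ambiguity
    for a in (out[1], out[3]):
        assert a.small_adduct in ("H3PO4", "H2SO4")
        assert "isobaric-ambiguity" in a.flags
        rival_names = {r.small_adduct for r in a.ambiguous_with}
        assert {"H3PO4", "H2SO4"} == rival_names | {a.small_adduct}
    # all matched within tolerance
    for a in out:
        assert abs(a.error_da) <= 1.5


def test_assignment_composition_strings():
    peaks = NeutralPeakList(np.array([14687.0]), np.array([1.0]))
    (a,) = assign_adducts(peaks, RNASE_A, [PT_TERPY], k_max=2)
    assert a.k == 2
    assert a.composition == "P + 2x[Pt(terpy-Ph)]"


def test_unassigned_peak_flagged():
    peaks = NeutralPeakList(np.array([13950.0]), np.array([1.0]))
    (a,) = assign_adducts(peaks, RNASE_A, [PT_TERPY], k_max=2)
    assert a.flags == ["unassigned"]
    assert math.isnan(a.predicted_da)


def test_isobaric_pair_not_flagged_when_rivals_are_resolved():
    """Candidates > 0.5 Da apart never trigger the ambiguity flag, even if
    both are within the matching tolerance."""
    # mono-adduct (14184.44) vs nothing else within 0.5 Da of it
    peaks = NeutralPeakList(np.array([14184.4]), np.array([1.0]),
                            tolerance_da=1.5)
    (a,) = assign_adducts(peaks, RNASE_A, [PT_TERPY], k_max=2)
    assert a.k == 1 and not a.flags


def test_mz_from_mass_and_inverse():
    m = 14304.0
    for z in (1, 8, 12):
        mz = mz_from_mass(m, z)
        assert z * mz - z * PROTON_MASS == pytest.approx(m, abs=1e-9)
    with pytest.raises(ValueError):
        mz_from_mass(m, 0)


@settings(max_examples=100, derandomize=True)
@given(
    m=st.floats(5000.0, 30000.0, allow_nan=False),
    z=st.integers(1, 30),
)
def test_mz_round_trip_property(m, z):
    mz = mz_from_mass(m, z)
    assert mz > 0
    assert z * mz - z * PROTON_MASS == pytest.approx(m, rel=1e-12)
    # adding a charge lowers m/z for masses above the proton mass
    if z >= 1:
        assert mz_from_mass(m, z + 1) < mz


def test_deconvolve_single_species_exact():
    from metallobind.simulate import simulate_esi_spectrum

    raw = simulate_esi_spectrum([(HEWL, 1.0)], sigma_rel=0.0)
    peaks = deconvolve_envelope(raw)
    assert peaks.masses_da.size == 1
    assert peaks.masses_da[0] == pytest.approx(HEWL, abs=0.01)


def test_deconvolve_two_species():
    from metallobind.simulate import simulate_esi_spectrum

    truth = [(RNASE_A, 1.0), (RNASE_A + PT_TERPY.mass_shift, 0.6)]
    raw = simulate_esi_spectrum(truth, sigma_rel=0.0)
    peaks = deconvolve_envelope(raw)
    assert peaks.masses_da.size == 2
    for (m_true, _), m_rec in zip(truth, peaks.masses_da):
        assert m_rec == pytest.approx(m_true, abs=1.0)


def test_deconvolve_empty_input():
    peaks = deconvolve_envelope(np.empty((0, 2)))
    assert peaks.masses_da.size == 0


def test_deconvolve_requires_min_charge_states():
    # two isolated peaks cannot satisfy the 3-charge-state requirement
    raw = np.array([[mz_from_mass(HEWL, 10), 1.0],
                    [mz_from_mass(HEWL, 11), 1.0]])
    with pytest.warns(UserWarning, match="no candidate"):
        peaks = deconvolve_envelope(raw)
    assert peaks.masses_da.size == 0


def test_peaklist_validation():
    with pytest.raises(ValueError):
        NeutralPeakList(np.array([1.0, 2.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        NeutralPeakList(np.array([-5.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        NeutralPeakList(np.array([5.0]), np.array([1.0]), tolerance_da=0.0)
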