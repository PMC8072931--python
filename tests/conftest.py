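"""Shared fixtures: noiseless forward-model data used across test modules."""

import numpy as np
import pytest

from metallobind import (
    build_isotherm,
    simulate_dsc,
    simulate_titration,
)


@pytest.fixture(scope="session")
def clean_series():
    """Noiseless 1:1 titration at K=1e4, delta_eps=-5000 (band-max scale)."""
    return simulate_titration(k=1.0e4, n=1.0, delta_eps=-5000.0, sigma_a=0.0)


@pytest.fixture(scope="session")
def clean_isotherm(clean_series):
    """Isotherm of `clean_series` read at the free-band maximum (378 nm),
    where the generator's delta_eps is exactly -5000."""
    return build_isotherm(clean_series, lambda_star=378.0)


@pytest.fixture(scope="session")
def clean_thermogram():
    """Noiseless two-state endotherm, dH=450 kJ/mol, T_d=350 K."""
    return simulate_dsc(t_d_k=350.0, dh=450.0, sigma_frac=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
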