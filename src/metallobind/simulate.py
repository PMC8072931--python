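"""Synthetic instrument data with known ground truth.

Every analysis stage in this package is exercised against simulated
inputs whose generating model is exactly the forward model the fitters
assume, so parameter recovery is a sharp correctness check:

* ``simulate_titration`` - differential UV-Vis titration of a metal
  complex with protein stock: per-addition dilution bookkeeping, the
  exact n-site mass-action equilibrium, Beer-Lambert spectra built from
  a Gaussian free band and a shifted/scaled bound band (which two-state
  mixing endows with an exact isosbestic point), additive absorbance
  noise.  Default concentrations follow a typical micro-syringe design:
  ~1.3e-4 M complex working solution titrated with 2.0e-3 M protein
  stock in 8.2 uL steps.

* ``simulate_dsc`` - two-state excess-heat-capacity endotherms, single
  population or weighted mixtures (the "shouldered" case), scanned
  over 20-95 C, Gaussian noise as a fraction of peak height.

* ``simulate_esi_spectrum`` - centroided positive-mode multi-charge
  envelopes: one peak per species and charge with a Gaussian abundance
  profile over charge states, clipped to the acquisition window,
  multiplicative intensity noise.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; sigma = 0 output is seed-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adducts import mz_from_mass
from .dsc import Thermogram, two_state_cp
from .titration import Spectrum, TitrationPoint, TitrationSeries, solve_equilibrium

__all__ = [
    "SimConfig",
    "simulate_titration",
    "simulate_dsc",
    "simulate_esi_spectrum",
    "isosbestic_wavelength",
]


@dataclass
class SimConfig:
    """Noise levels and the master seed shared by all simulators.

    Defaults are instrument-realistic: 0.002 AU absorbance noise, DSC
    noise at 1% of peak height, 2% relative MS intensity noise.
    """

    seed: int = 0
    sigma_a: float = 0.002           # AU
    sigma_cp_frac: float = 0.01      # fraction of Cp peak height
    sigma_ms_rel: float = 0.02      # relative intensity
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.sigma_a, self.sigma_cp_frac, self.sigma_ms_rel) < 0:
            raise ValueError("noise levels must be non-negative")


def _gaussian_band(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def isosbestic_wavelength(
    band_center_nm: float,
    band_width_nm: float,
    eps_max: float,
    delta_eps: float,
    bound_shift_nm: float,
) -> float:
    """Wavelength where the free and bound bands cross (exact, by algebra).

    With equal-width Gaussian bands the crossing condition is linear in
    wavelength: u = (d^2 - 2 w^2 ln s)/(2 d) with u = lambda - center,
    d the bound-band shift, s the bound-band scale factor.
    """
    if bound_shift_nm == 0:
        raise ValueError("zero band shift: bands never cross")
    s = _bound_scale(eps_max, delta_eps, band_width_nm, bound_shift_nm)
    d, w = bound_shift_nm, band_width_nm
    u = (d * d - 2.0 * w * w * np.log(s)) / (2.0 * d)
    return band_center_nm + u


def _bound_scale(eps_max, delta_eps, width, shift):
    """Scale factor making eps_bound - eps_free = delta_eps at the free max."""
    s = (eps_max + delta_eps) / (eps_max * np.exp(-0.5 * (shift / width) ** 2))
    if s <= 0:
        raise ValueError("delta_eps too negative: bound band would be non-physical")
    return s


def simulate_titration(
    k: float = 1.0e4,
    n: float = 1.0,
    delta_eps: float = -5000.0,
    eps_max: float = 1.0e4,
    band_center_nm: float = 378.0,
    band_width_nm: float = 30.0,
    bound_shift_nm: float = 3.0,
    c_ptl0: float = 1.3e-4,
    protein_stock: float = 2.0e-3,
    additions: int = 15,
    addition_volume_l: float = 8.2e-6,
    v0_l: float = 1.15e-3,
    sigma_a: float = 0.0,
    seed: int = 0,
    wavelength_nm: Optional[np.ndarray] = None,
    path_cm: float = 1.0,
) -> TitrationSeries:
    """Simulate a differential titration of complex with protein stock.

    Returns a TitrationSeries whose point 0 is the protein-free working
    solution; each subsequent point adds `addition_volume_l` of protein
    stock, updates the in-cell analytical totals for dilution, solves
    the n-equivalent-site equilibrium exactly and composes the spectrum
    A = eps_free*[free] + eps_bound*[bound] (the protein itself absorbs
    nothing, emulating the matched reference cell).  Gaussian noise of
    standard deviation `sigma_a` AU is added per spectrum sample.
    """
    if min(k, n, eps_max, c_ptl0, protein_stock, v0_l, path_cm) <= 0:
        raise ValueError("physical parameters must be positive")
    if sigma_a < 0 or additions < 0:
        raise ValueError("sigma_a and additions must be non-negative")
    if k * protein_stock < 0.1:
        warnings.warn("unsaturated scenario: K * protein_stock < 0.1",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    if wavelength_nm is None:
        wavelength_nm = np.arange(300.0, 501.0, 1.0)
    wl = np.asarray(wavelength_nm, dtype=float)

    eps_free = eps_max * _gaussian_band(wl, band_center_nm, band_width_nm)
    scale = _bound_scale(eps_max, delta_eps, band_width_nm, bound_shift_nm)
    eps_bound = scale * eps_max * _gaussian_band(
        wl, band_center_nm + bound_shift_nm, band_width_nm)

    points = []
    for i in range(additions + 1):
        v_add = i * addition_volume_l
        v = v0_l + v_add
        c_ptl = c_ptl0 * v0_l / v
        c_prot = protein_stock * v_add / v
        x = solve_equilibrium(c_ptl, c_prot, k, n)
        absorb = path_cm * (eps_free * (c_ptl - x) + eps_bound * x)
        if sigma_a > 0:
            absorb = absorb + rng.normal(0.0, sigma_a, size=wl.shape)
        points.append(TitrationPoint(
            c_ptl=c_ptl, c_protein=c_prot,
            spectrum=Spectrum(wl, absorb, path_cm), v_added_l=v_add,
        ))
    return TitrationSeries(points=points, v0_l=v0_l)


def simulate_dsc(
    t_d_k: float = 350.0,
    dh: float = 450.0,
    dcp: float = 0.0,
    sigma_frac: float = 0.0,
    t_range_c: tuple = (20.0, 95.0),
    step_k: float = 0.1,
    seed: int = 0,
    populations: Optional[Sequence[tuple]] = None,
    protein_molar: float = 2.0e-4,
    scan_rate_k_min: float = 0.5,
) -> Thermogram:
    """Simulate a two-state (or mixture) excess-heat-capacity thermogram.

    `populations`, when given, is a sequence of (weight, T_d_K, dH)
    tuples whose weights must sum to 1; otherwise a single population
    at (`t_d_k`, `dh`) is used.  Noise is Gaussian with standard
    deviation `sigma_frac` times the noiseless peak height.
    """
    if step_k <= 0 or step_k > 0.2:
        raise ValueError("step must be in (0, 0.2] K")
    if not (15.0 <= t_range_c[0] < t_range_c[1] <= 100.0):
        raise ValueError("temperature range must lie within 15-100 C")
    if populations is None:
        populations = [(1.0, t_d_k, dh)]
    weights = np.array([p[0] for p in populations], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("population weights must sum to 1")
    rng = np.random.default_rng(seed)
    t = np.arange(t_range_c[0] + 273.15, t_range_c[1] + 273.15 + 0.5 * step_k,
                  step_k)
    cp = np.zeros_like(t)
    for pop in populations:
        w, td_i, dh_i = pop[:3]
        dcp_i = pop[3] if len(pop) > 3 else dcp
        cp += w * two_state_cp(t, dh_i, td_i, dcp_i)
    if sigma_frac > 0:
        cp = cp + rng.normal(0.0, sigma_frac * float(np.max(cp)), size=t.shape)
    return Thermogram(t, cp, protein_molar, scan_rate_k_min)


def simulate_esi_spectrum(
    species: Sequence[tuple],
    z_range: Sequence[int] = range(8, 15),
    envelope_center_z: float = 11.0,
    envelope_width_z: float = 2.0,
    peak_fwhm_mz: float = 1.0,
    sigma_rel: float = 0.0,
    seed: int = 0,
    mz_window: tuple = (1000.0, 2600.0),
) -> np.ndarray:
    """Simulate a centroided positive-mode ESI envelope.

    `species` is a sequence of (neutral mass Da, abundance) pairs.  For
    each species and each charge z in `z_range` a centroid is placed at
    (M + z m_p)/z with intensity abundance * exp(-(z - center)^2 /
    (2 width^2)); centroids closer than `peak_fwhm_mz`/2 are merged
    intensity-weighted (unresolved peaks), the acquisition window is
    applied, and multiplicative N(1, sigma_rel) noise scales each
    intensity.  Returns an (n, 2) array of (m/z, intensity) sorted by
    m/z.
    """
    rng = np.random.default_rng(seed)
    raw = []
    for mass, abundance in species:
        if mass <= 0:
            raise ValueError("species masses must be positive")
        if abundance <= 0:
            continue
        for z in z_range:
            inten = abundance * np.exp(
                -0.5 * ((z - envelope_center_z) / envelope_width_z) ** 2)
            raw.append((mz_from_mass(mass, z), inten))
    raw.sort()
    # merge unresolved centroids
    merged = []
    for mz, inten in raw:
        if merged and mz - merged[-1][0] < 0.5 * peak_fwhm_mz:
            m0, i0 = merged[-1]
            total = i0 + inten
            merged[-1] = ((m0 * i0 + mz * inten) / total, total)
        else:
            merged.append((mz, inten))
    out = [(mz, i) for mz, i in merged if mz_window[0] <= mz <= mz_window[1]]
    if raw and not out:
        warnings.warn("all simulated peaks fall outside the acquisition window",
                      stacklevel=2)
    arr = np.array(out, dtype=float).reshape(-1, 2)
    if sigma_rel > 0 and arr.size:
        arr[:, 1] *= rng.normal(1.0, sigma_rel, size=arr.shape[0])
        arr[:, 1] = np.maximum(arr[:, 1], 0.0)
    return arr
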