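"""Spectrophotometric binding analysis for 1:1 metal-complex/protein equilibria.

A Pt(II) complex (PtL) binding a protein P,

    P + PtL  <=>  P-PtL,     K = [P-PtL] / ([P][PtL])

is followed by differential UV-Vis titration: protein stock is added to a
cuvette holding the complex (and to the reference cell, so the protein's
own absorbance cancels), and the differential absorbance

    dA = A - eps_PtL * C_PtL * l

at an analysis wavelength tracks the bound fraction, dA = d_eps * x * l,
where x is the bound-adduct molarity and d_eps = eps_bound - eps_free is
the (signed) molar-absorptivity change — negative for hypochromism.

Two linearized estimators are implemented:

* an iterative double-reciprocal estimator.  The mass-action law for a
  1:1 equilibrium rearranges exactly to

      C_PtL*C_P/dA + dA/d_eps^2 = (C_PtL + C_P)/d_eps + 1/(K*d_eps)

  Since d_eps is unknown, iteration 0 drops the dA/d_eps^2 term, reads
  d_eps from the reciprocal slope, and subsequent passes re-add the term
  until d_eps converges; K is then slope/intercept.

* a Scatchard-type estimator for n independent equivalent sites,

      C_P*(C_PtL*d_eps - dA)/dA = 1/(n*K) + (C_PtL*d_eps - dA)/(n*d_eps)

  whose slope and intercept give the site count n and affinity K, with
  d_eps supplied from the isotherm amplitude (or the iterative fit).

Both linearizations are exact on model data; a direct nonlinear fit of
dA = d_eps * x(K) (with x from the closed-form mass-action solution)
serves as an independent oracle and exposes linearization bias under
noise.  All concentrations are the per-point analytical totals actually
in the cell, so the equations hold exactly even as dilution shifts C_PtL
across additions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

import lmfit

__all__ = [
    "Spectrum",
    "TitrationPoint",
    "TitrationSeries",
    "BindingIsotherm",
    "BindingFit1to1",
    "ScatchardFit",
    "correct_dilution",
    "concentration_from_a280",
    "build_isotherm",
    "solve_equilibrium",
    "fit_eq2_iterative",
    "fit_eq3_scatchard",
    "nls_oracle_fit",
    "diff_spectra",
    "runs_test",
]

MIN_POINTS = 4  # fewer protein-bearing points under-determines the regressions


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelength and absorbance must be equal-length 1-D arrays")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.path_cm <= 0:
            raise ValueError("path length must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", ab)

    def at(self, wavelength: float) -> float:
        """Absorbance at `wavelength`, linearly interpolated on the grid."""
        wl = self.wavelength_nm
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValueError(
                f"wavelength {wavelength} nm outside spectrum range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength, wl, self.absorbance))


@dataclass(frozen=True)
class TitrationPoint:
    """One titration addition: in-cell analytical totals plus the spectrum.

    ``c_ptl`` and ``c_protein`` are the total analytical molarities of
    complex and protein actually present in the cell at this point, i.e.
    already accounting for the dilution produced by the cumulative added
    titrant volume ``v_added_l``.
    """

    c_ptl: float
    c_protein: float
    spectrum: Spectrum
    v_added_l: float = 0.0

    def __post_init__(self) -> None:
        if self.c_ptl < 0 or self.c_protein < 0:
            raise ValueError("analytical concentrations must be non-negative")
        if self.v_added_l < 0:
            raise ValueError("added volume must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration, point 0 protein-free (defines eps_PtL)."""

    points: Sequence[TitrationPoint]
    lambda_star_nm: Optional[float] = None
    v0_l: float = 1.0e-3

    def __post_init__(self) -> None:
        pts = list(self.points)
        if not pts:
            raise ValueError("titration series needs at least one point")
        if pts[0].c_protein != 0:
            raise ValueError("point 0 must be protein-free (defines eps_PtL)")
        cp = [p.c_protein for p in pts]
        if any(b < a for a, b in zip(cp, cp[1:])):
            raise ValueError("protein concentration must be non-decreasing")
        if self.v0_l <= 0:
            raise ValueError("initial cell volume must be positive")
        object.__setattr__(self, "points", tuple(pts))

    def default_lambda_star(self) -> float:
        """Analysis wavelength: argmax |dA| between first and last spectrum.

        The free-complex absorptivity spectrum is read off point 0, so
        dA(lambda) = A_last(lambda) - eps_PtL(lambda) * C_PtL_last * l.
        """
        first, last = self.points[0], self.points[-1]
        if first.c_ptl <= 0:
            raise ValueError("point 0 has zero complex; cannot define eps_PtL")
        wl = first.spectrum.wavelength_nm
        a_last = np.interp(wl, last.spectrum.wavelength_nm, last.spectrum.absorbance)
        eps_free = first.spectrum.absorbance / (first.c_ptl * first.spectrum.path_cm)
        da = a_last - eps_free * last.c_ptl * last.spectrum.path_cm
        return float(wl[np.argmax(np.abs(da))])


@dataclass(frozen=True)
class BindingIsotherm:
    """dA at the analysis wavelength vs analytical totals (l = 1 cm scale)."""

    c_ptl: np.ndarray
    c_protein: np.ndarray
    delta_a: np.ndarray
    lambda_star_nm: float
    eps_ptl: float

    def __post_init__(self) -> None:
        for name in ("c_ptl", "c_protein", "delta_a"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.c_ptl.shape == self.c_protein.shape == self.delta_a.shape):
            raise ValueError("isotherm arrays must share a shape")


@dataclass
class BindingFit1to1:
    """Result of the 1:1 binding-constant estimation."""

    k: float                      # association constant, M^-1
    delta_eps: float              # signed amplitude, M^-1 cm^-1
    eps_ptl: float                # free-complex absorptivity at lambda*
    n_iter: int = 0
    delta_eps_trace: list = field(default_factory=list)
    slope: float = math.nan
    intercept: float = math.nan
    slope_stderr: float = math.nan
    intercept_stderr: float = math.nan
    k_stderr: float = math.nan
    delta_eps_stderr: float = math.nan
    converged: bool = True
    k_reliable: bool = True
    flags: list = field(default_factory=list)
    runs_test_p: float = math.nan

    @property
    def eps_bound(self) -> float:
        return self.eps_ptl + self.delta_eps


@dataclass
class ScatchardFit:
    """Result of the equivalent-sites Scatchard analysis."""

    n_sites: float
    k: float
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    n_stderr: float = math.nan
    k_stderr: float = math.nan
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations


def correct_dilution(raw: Spectrum, v0: float, v_added: float) -> Spectrum:
    """Rescale a spectrum onto the pre-dilution concentration scale.

    Multiplies every absorbance by (v0 + v_added)/v0, undoing the signal
    loss caused by titrant dilution (for workflows that analyse against
    the initial complex concentration).
    """
    if v0 <= 0:
        raise ValueError("initial volume must be positive")
    if v_added < 0:
        raise ValueError("added volume must be non-negative")
    factor = (v0 + v_added) / v0
    return Spectrum(raw.wavelength_nm, raw.absorbance * factor, raw.path_cm)


def concentration_from_a280(a: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert protein molarity from A280 (e.g. eps 38,940 for HEWL,
    8,640 M^-1 cm^-1 for RNase A)."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    if a < 0:
        raise ValueError("absorbance must be non-negative")
    return a / (epsilon * path_cm)


def solve_equilibrium(c_ptl: float, c_protein: float, k: float, n: float = 1.0):
    """Bound-complex molarity x for n independent equivalent sites.

    Mass action with site concentration n*C_P and ligand depletion gives

        K x^2 - (K (C_PtL + n C_P) + 1) x + K n C_P C_PtL = 0

    whose physically meaningful (smaller) root is returned in the
    cancellation-free form x = 2c / (b + sqrt(b^2 - 4ac)).  Vectorized
    over the concentration arguments; n = 1 is the plain 1:1 case.
    """
    if n <= 0:
        raise ValueError("site count n must be positive")
    if np.any(np.asarray(k) < 0):
        raise ValueError("K must be non-negative")
    c_ptl = np.asarray(c_ptl, dtype=float)
    c_protein = np.asarray(c_protein, dtype=float)
    if np.any(c_ptl < 0) or np.any(c_protein < 0):
        raise ValueError("concentrations must be non-negative")
    sites = n * c_protein
    b = k * (c_ptl + sites) + 1.0
    c = k * sites * c_ptl
    disc = b * b - 4.0 * k * c
    x = 2.0 * c / (b + np.sqrt(np.maximum(disc, 0.0)))
    x = np.minimum(x, np.minimum(c_ptl, sites))
    return x if x.ndim else float(x)


def build_isotherm(
    series: TitrationSeries,
    epsilon_ptl: Optional[float] = None,
    lambda_star: Optional[float] = None,
) -> BindingIsotherm:
    """Extract the binding isotherm dA(C_protein) at the analysis wavelength.

    eps_PtL defaults to A0(lambda*)/(l * C_PtL,0) from the protein-free
    point; dA is path-length-normalized to l = 1 cm.  Point 0 has dA = 0
    by construction.
    """
    if len(series.points) < MIN_POINTS:
        raise ValueError(
            f"titration series needs >= {MIN_POINTS} points, got {len(series.points)}"
        )
    lam = lambda_star if lambda_star is not None else (
        series.lambda_star_nm if series.lambda_star_nm is not None
        else series.default_lambda_star()
    )
    p0 = series.points[0]
    if epsilon_ptl is None:
        if p0.c_ptl <= 0:
            raise ValueError("cannot infer eps_PtL: point 0 has zero complex")
        epsilon_ptl = p0.spectrum.at(lam) / (p0.spectrum.path_cm * p0.c_ptl)
    c_ptl, c_prot, da = [], [], []
    for p in series.points:
        a_norm = p.spectrum.at(lam) / p.spectrum.path_cm  # to l = 1 cm
        c_ptl.append(p.c_ptl)
        c_prot.append(p.c_protein)
        da.append(a_norm - epsilon_ptl * p.c_ptl)
    return BindingIsotherm(
        np.array(c_ptl), np.array(c_prot), np.array(da),
        lambda_star_nm=float(lam), eps_ptl=float(epsilon_ptl),
    )


def diff_spectra(s1: Spectrum, s2: Spectrum):
    """Difference spectrum s2 - s1 on the common grid.

    Returns (common wavelength grid, difference, max |difference|,
    wavelength of the max).  Used as a qualitative stability probe, e.g.
    for the growth of a new band on ligand exchange.
    """
    lo = max(s1.wavelength_nm[0], s2.wavelength_nm[0])
    hi = min(s1.wavelength_nm[-1], s2.wavelength_nm[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint wavelength ranges")
    grid = s1.wavelength_nm[(s1.wavelength_nm >= lo) & (s1.wavelength_nm <= hi)]
    a1 = np.interp(grid, s1.wavelength_nm, s1.absorbance)
    a2 = np.interp(grid, s2.wavelength_nm, s2.absorbance)
    diff = a2 - a1
    imax = int(np.argmax(np.abs(diff)))
    return grid, diff, float(np.abs(diff[imax])), float(grid[imax])


def runs_test(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs-test p-value on residual signs.

    A small p flags systematic curvature ("distorted isotherm") that the
    straight-line model cannot represent.  Zero residuals are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    if signs.size < 2:
        return float("nan")
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n * n * (n - 1.0))
    if var <= 0:
        return float("nan")
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# estimators


def _usable_points(iso: BindingIsotherm):
    """Protein-bearing points with non-zero dA of the dominant sign."""
    mask = iso.c_protein > 0
    zero_da = mask & (iso.delta_a == 0)
    if np.any(zero_da):
        warnings.warn(
            f"dropping {int(zero_da.sum())} point(s) with dA = 0 at non-zero protein",
            stacklevel=3,
        )
        mask &= iso.delta_a != 0
    da = iso.delta_a[mask]
    if da.size:
        dominant = 1.0 if np.sum(da > 0) >= np.sum(da < 0) else -1.0
        wrong = np.sign(iso.delta_a) == -dominant
        if np.any(mask & wrong):
            warnings.warn(
                "dropping point(s) whose dA sign opposes the dominant sign "
                "(possible isosbestic drift)",
                stacklevel=3,
            )
            mask &= ~wrong
    if int(mask.sum()) < MIN_POINTS:
        raise ValueError(
            f"need >= {MIN_POINTS} usable protein-bearing points, have {int(mask.sum())}"
        )
    return iso.c_ptl[mask], iso.c_protein[mask], iso.delta_a[mask]


def _jackknife_se(iso: BindingIsotherm, estimator) -> float:
    """Leave-one-out jackknife standard error of a scalar estimator.

    Deterministic and procedure-aware: each replicate re-runs the full
    fit, so the error estimate reflects the reciprocal transform's
    heteroskedasticity and the iterative d_eps coupling that the
    regression delta method misses.
    """
    idx = np.where(iso.c_protein > 0)[0]
    values = []
    for drop in idx:
        keep = np.ones(iso.c_ptl.size, dtype=bool)
        keep[drop] = False
        sub = BindingIsotherm(
            iso.c_ptl[keep], iso.c_protein[keep], iso.delta_a[keep],
            iso.lambda_star_nm, iso.eps_ptl,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values.append(estimator(sub))
        except (ValueError, ZeroDivisionError):
            continue
    vals = np.asarray([v for v in values if np.isfinite(v)])
    if vals.size < 3:
        return math.nan
    n = vals.size
    return float(np.sqrt((n - 1) / n * np.sum((vals - vals.mean()) ** 2)))


def fit_eq2_iterative(
    iso: BindingIsotherm,
    tol: float = 1e-6,
    max_iter: int = 100,
    accelerate: bool = True,
    se_method: str = "jackknife",
) -> BindingFit1to1:
    """Iterative double-reciprocal estimate of (K, d_eps) for 1:1 binding.

    Regresses Y on X = C_PtL + C_P, where iteration 0 uses
    Y0 = C_PtL*C_P/dA (the quadratic term dropped) and later passes use
    Y = Y0 + dA/d_eps^2 with d_eps = 1/slope from the previous pass,
    until d_eps changes by less than `tol` (relative).  At convergence
    K = slope/intercept.

    The plain update d_eps <- 1/slope is a linearly convergent fixed
    point whose contraction factor approaches (and near the
    stoichiometric large-K limit exceeds) 1; with `accelerate` an
    Aitken delta-squared extrapolation is applied after every two plain
    updates (Steffensen scheme), which reaches the fixed point at
    second order and also converges onto locally repelling fixed
    points.  Because the self-consistency equation can develop a
    spurious second root in the near-stoichiometric regime, the
    iteration is run from two starts — the term-free iteration-0
    estimate and a saturation-amplitude estimate dA_max/min(C_PtL,
    n C_P) — and the root whose final regression has the smaller
    residual sum of squares wins (the exact root has zero residual on
    model data).

    The intercept carries the 1/(K d_eps) information; when its t-ratio
    falls below 2 (typical of unsaturated isotherms) K is flagged
    unreliable.  `se_method` selects the K standard error: "jackknife"
    (default; leave-one-out over isotherm points, coverage-calibrated)
    or "delta" (regression delta method, fast but optimistic under the
    reciprocal transform's noise amplification).
    """
    c_ptl, c_prot, da = _usable_points(iso)
    x = c_ptl + c_prot
    y0 = c_ptl * c_prot / da

    flags: list[str] = []
    reg0 = stats.linregress(x, y0)
    if reg0.slope == 0:
        raise ValueError("zero slope in iteration 0; dA carries no trend")

    def g(d: float) -> float:
        reg = stats.linregress(x, y0 + da / (d * d))
        if reg.slope == 0:
            raise ValueError("zero slope during iteration")
        return 1.0 / reg.slope

    def iterate(d_start: float):
        trace = [d_start]
        d = d_start
        converged = False
        n_iter = 0
        while n_iter < max_iter:
            d1 = g(d)
            n_iter += 1
            trace.append(d1)
            if abs(d1 - d) / abs(d1) < tol:
                d = d1
                converged = True
                break
            if not accelerate or n_iter >= max_iter:
                d = d1
                continue
            d2 = g(d1)
            n_iter += 1
            trace.append(d2)
            if abs(d2 - d1) / abs(d2) < tol:
                d = d2
                converged = True
                break
            denom = d2 - 2.0 * d1 + d
            acc = d2 - (d2 - d1) ** 2 / denom if denom != 0 else d2
            d = acc if np.isfinite(acc) and acc * d2 > 0 else d2
            if d != d2:
                trace.append(d)
        y = y0 + da / (d * d)
        reg = stats.linregress(x, y)
        sse = float(np.sum((y - reg.slope * x - reg.intercept) ** 2))
        return d, trace, n_iter, converged, reg, sse

    i_sat = int(np.argmax(np.abs(da)))
    d_amp = da[i_sat] / min(c_ptl[i_sat], c_prot[i_sat])
    results = [iterate(1.0 / reg0.slope)]
    if np.isfinite(d_amp) and d_amp != 0:
        results.append(iterate(d_amp))
    usable = [r for r in results if np.isfinite(r[5])] or results
    converged_runs = [r for r in usable if r[3]] or usable
    delta_eps, trace, n_iter, converged, reg, _ = min(
        converged_runs, key=lambda r: r[5])
    if not converged:
        flags.append("no-convergence")

    slope, intercept = reg.slope, reg.intercept
    k = slope / intercept if intercept != 0 else math.inf
    k_reliable = True
    if intercept == 0 or reg.intercept_stderr == 0 and intercept == 0:
        k_reliable = False
    elif reg.intercept_stderr > 0 and abs(intercept / reg.intercept_stderr) < 2:
        k_reliable = False
        flags.append("intercept-t<2: K unreliable (unsaturated isotherm?)")

    # delta-method errors: d_eps = 1/slope, K = slope/intercept, with
    # OLS covariance cov(slope, intercept) = -mean(x) * var(slope)
    de_err = reg.stderr / slope**2 if reg.stderr else math.nan
    if intercept != 0 and reg.stderr is not None:
        cov_si = -float(np.mean(x)) * reg.stderr**2
        var_rel = (
            (reg.stderr / slope) ** 2
            + (reg.intercept_stderr / intercept) ** 2
            - 2.0 * cov_si / (slope * intercept)
        )
        k_err = abs(k) * math.sqrt(max(var_rel, 0.0))
    else:
        k_err = math.nan
    if se_method == "jackknife":
        jk = _jackknife_se(
            iso,
            lambda sub: fit_eq2_iterative(
                sub, tol=tol, max_iter=max_iter, accelerate=accelerate,
                se_method="delta").k,
        )
        if np.isfinite(jk):
            k_err = jk

    y_final = y0 + da / (delta_eps * delta_eps)
    residuals = y_final - (slope * x + intercept)
    p_runs = runs_test(residuals)
    if not math.isnan(p_runs) and p_runs < 0.05:
        flags.append("runs-test: residuals non-random (distorted isotherm?)")

    return BindingFit1to1(
        k=k, delta_eps=delta_eps, eps_ptl=iso.eps_ptl,
        n_iter=n_iter, delta_eps_trace=trace,
        slope=slope, intercept=intercept,
        slope_stderr=reg.stderr, intercept_stderr=reg.intercept_stderr,
        k_stderr=k_err, delta_eps_stderr=abs(de_err),
        converged=converged, k_reliable=k_reliable, flags=flags,
        runs_test_p=p_runs,
    )


def fit_eq3_scatchard(
    iso: BindingIsotherm,
    delta_eps: float,
    se_method: str = "jackknife",
) -> ScatchardFit:
    """Equivalent-sites Scatchard analysis given the isotherm amplitude d_eps.

    Regresses Y = C_P (C_PtL d_eps - dA)/dA on X = C_PtL d_eps - dA;
    slope = 1/(n d_eps), intercept = 1/(n K), so n = 1/(slope d_eps) and
    K = slope d_eps / intercept.  Standard errors by leave-one-out
    jackknife (default) or the regression delta method.
    """
    if delta_eps == 0:
        raise ValueError("delta_eps must be non-zero")
    c_ptl, c_prot, da = _usable_points(iso)
    if np.sign(delta_eps) != np.sign(np.median(da)):
        raise ValueError("delta_eps sign inconsistent with the isotherm dA")
    x = c_ptl * delta_eps - da
    y = c_prot * x / da
    flags: list[str] = []
    xr = np.abs(x)
    if np.min(xr) > 0 and np.max(xr) / np.min(xr) < 10:
        flags.append("X-range < 1 decade: n poorly determined")
    reg = stats.linregress(x, y)
    if reg.slope == 0:
        raise ValueError("zero Scatchard slope")
    n_sites = 1.0 / (reg.slope * delta_eps)
    k = reg.slope * delta_eps / reg.intercept if reg.intercept != 0 else math.inf
    n_err = abs(n_sites) * (reg.stderr / abs(reg.slope)) if reg.stderr else math.nan
    if reg.intercept != 0 and reg.stderr is not None:
        cov_si = -float(np.mean(x)) * reg.stderr**2
        var_rel = (
            (reg.stderr / reg.slope) ** 2
            + (reg.intercept_stderr / reg.intercept) ** 2
            - 2.0 * cov_si / (reg.slope * reg.intercept)
        )
        k_err = abs(k) * math.sqrt(max(var_rel, 0.0))
    else:
        k_err = math.nan
    if se_method == "jackknife":
        jk_k = _jackknife_se(
            iso, lambda s: fit_eq3_scatchard(s, delta_eps, se_method="delta").k)
        jk_n = _jackknife_se(
            iso,
            lambda s: fit_eq3_scatchard(s, delta_eps, se_method="delta").n_sites)
        if np.isfinite(jk_k):
            k_err = jk_k
        if np.isfinite(jk_n):
            n_err = jk_n
    if reg.intercept_stderr and reg.intercept != 0 and \
            abs(reg.intercept / reg.intercept_stderr) < 2:
        flags.append("intercept-t<2: K unreliable")
    return ScatchardFit(
        n_sites=n_sites, k=k,
        slope=reg.slope, intercept=reg.intercept,
        slope_stderr=reg.stderr, intercept_stderr=reg.intercept_stderr,
        n_stderr=n_err, k_stderr=k_err, flags=flags,
    )


def nls_oracle_fit(iso: BindingIsotherm, n: float = 1.0) -> BindingFit1to1:
    """Direct nonlinear least squares of dA = d_eps * x(K) (independent oracle).

    Minimizes sum (dA_obs - d_eps * x(K, C_PtL, C_P))^2 over (log10 K,
    d_eps) by Levenberg-Marquardt from the best point of a coarse
    log-spaced K grid; reports asymptotic standard errors.  Exists to
    cross-check the linearized estimators, so it shares nothing with
    them beyond the mass-action solver.
    """
    c_ptl, c_prot, da = _usable_points(iso)
    if np.all(c_prot == 0):
        raise ValueError("no protein-bearing points: nothing to fit")

    def model(log10_k, d_eps):
        x = solve_equilibrium(c_ptl, c_prot, 10.0 ** log10_k, n)
        return d_eps * x

    best = None
    for lk in np.linspace(1.0, 8.0, 15):
        x = solve_equilibrium(c_ptl, c_prot, 10.0 ** lk, n)
        denom = float(np.dot(x, x))
        if denom == 0:
            continue
        de = float(np.dot(x, da)) / denom
        sse = float(np.sum((da - de * x) ** 2))
        if best is None or sse < best[0]:
            best = (sse, lk, de)
    if best is None:
        raise ValueError("degenerate isotherm: bound fraction identically zero")
    _, lk0, de0 = best

    params = lmfit.Parameters()
    params.add("log10_k", value=lk0, min=-2.0, max=16.0)
    params.add("d_eps", value=de0)

    def resid(p):
        return da - model(p["log10_k"].value, p["d_eps"].value)

    out = lmfit.minimize(resid, params, method="leastsq")
    lk = out.params["log10_k"].value
    de = out.params["d_eps"].value
    k = 10.0 ** lk
    lk_err = out.params["log10_k"].stderr
    de_err = out.params["d_eps"].stderr
    k_err = k * math.log(10) * lk_err if lk_err is not None else math.nan
    flags: list[str] = []
    reliable = True
    if lk_err is None or not np.isfinite(lk_err) or (k_err / k) > 1.0:
        flags.append("flat objective: K poorly constrained (unsaturated data)")
        reliable = False
    return BindingFit1to1(
        k=k, delta_eps=de, eps_ptl=iso.eps_ptl,
        n_iter=int(out.nfev), k_stderr=k_err,
        delta_eps_stderr=de_err if de_err is not None else math.nan,
        converged=bool(out.success), k_reliable=reliable, flags=flags,
    )
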