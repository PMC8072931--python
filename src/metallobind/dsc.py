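"""Two-state DSC unfolding thermodynamics.

A differential scanning calorimeter records the excess molar heat
capacity Cp_exc(T) of a protein solution relative to the native-state
baseline.  For a reversible two-state transition N <=> D with van't Hoff
enthalpy dH_vH and midpoint T_d,

    dG(T) = dH_vH (1 - T/T_d) + dCp [(T - T_d) - T ln(T/T_d)]
    K_eq  = exp(-dG / (R T));   f_D = K_eq / (1 + K_eq)
    Cp_exc(T) = dH(T) df_D/dT + f_D dCp,   dH(T) = dH_vH + dCp (T - T_d)

with the analytic derivative

    df_D/dT = dH(T) K_eq / (R T^2 (1 + K_eq)^2).

Model-free observables are the calorimetric enthalpy (area under the
peak), the denaturation temperature T_d (peak maximum), and the
denaturation entropy dS = dH / T_d from dG(T_d) = 0.  The fitted van't
Hoff enthalpy probes cooperativity via the dH_vH/dH_cal ratio; a fit
whose RMS residual exceeds 5% of the peak height is declared FAILED,
the situation expected when the sample is a statistical mixture of
differently-liganded protein populations rather than a single two-state
species.

Internally everything is Kelvin and kJ/mol; file I/O converts from the
instrument's Celsius convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

import lmfit

__all__ = [
    "R_KJ",
    "Thermogram",
    "TwoStateParams",
    "two_state_cp",
    "subtract_baseline",
    "integrate_enthalpy",
    "find_td",
    "fit_two_state",
    "entropy_at_td",
    "correct_native_loss",
]

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA).
R_KJ: float = 8.314462618e-3

#: Fits with RMS residual above this fraction of the peak height are FAILED.
FAIL_RESIDUAL_FRAC: float = 0.05


@dataclass(frozen=True)
class Thermogram:
    """Excess molar heat capacity on a strictly increasing Kelvin grid."""

    temperature_k: np.ndarray
    cp_exc: np.ndarray           # kJ mol^-1 K^-1
    protein_molar: float = 2.0e-4
    scan_rate_k_min: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_k, dtype=float)
        cp = np.asarray(self.cp_exc, dtype=float)
        if t.ndim != 1 or t.shape != cp.shape:
            raise ValueError("temperature and Cp_exc must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature_k", t)
        object.__setattr__(self, "cp_exc", cp)

    @property
    def temperature_c(self) -> np.ndarray:
        return self.temperature_k - 273.15


@dataclass
class TwoStateParams:
    """Thermodynamic parameters of a two-state unfolding transition."""

    t_d_k: float                     # midpoint / peak temperature, K
    dh_cal: float = math.nan         # calorimetric enthalpy, kJ/mol
    dh_vh: float = math.nan          # van't Hoff enthalpy, kJ/mol
    dcp: float = 0.0                 # unfolding heat-capacity step, kJ/mol/K
    ds_at_td: float = math.nan       # dH/T_d, kJ/mol/K
    cooperativity_ratio: float = math.nan  # dH_vH / dH_cal
    rms_residual: float = math.nan   # same units as Cp_exc
    peak_height: float = math.nan
    status: str = "OK"               # "OK" | "FAILED"
    flags: list = field(default_factory=list)


def two_state_cp(
    temperature_k,
    dh_vh: float,
    t_d_k: float,
    dcp: float = 0.0,
):
    """Excess molar heat capacity of the two-state model (kJ/mol/K).

    At T = T_d with dCp = 0 the unfolded fraction is 1/2 and the peak
    height is dH_vH^2 / (4 R T_d^2).
    """
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    if t_d_k <= 0:
        raise ValueError("T_d must be positive (Kelvin)")
    dg = dh_vh * (1.0 - t / t_d_k) + dcp * ((t - t_d_k) - t * np.log(t / t_d_k))
    # exp(-dG/RT) can overflow far below T_d for large dH; clip the argument
    arg = np.clip(-dg / (R_KJ * t), -700.0, 700.0)
    k_eq = np.exp(arg)
    f_d = k_eq / (1.0 + k_eq)
    dh_t = dh_vh + dcp * (t - t_d_k)
    dfdt = dh_t * k_eq / (R_KJ * t * t * (1.0 + k_eq) ** 2)
    cp = dh_t * dfdt + f_d * dcp
    return cp if cp.ndim else float(cp)


def subtract_baseline(
    raw: Thermogram,
    pre_window: Optional[tuple] = None,
    post_window: Optional[tuple] = None,
    n_iter: int = 2,
) -> Thermogram:
    """Remove a sigmoidal progress baseline.

    Straight lines are fitted in the pre- and post-transition windows
    (defaults: first and last 10% of the scan) and connected by the
    normalized running integral of the baseline-corrected signal — the
    unfolding progress — iterated `n_iter` times so the progress curve
    is computed on an already-flattened signal.
    """
    t, cp = raw.temperature_k, raw.cp_exc
    if pre_window is None:
        pre_window = (t[0], t[0] + 0.10 * (t[-1] - t[0]))
    if post_window is None:
        post_window = (t[-1] - 0.10 * (t[-1] - t[0]), t[-1])
    pre_mask = (t >= pre_window[0]) & (t <= pre_window[1])
    post_mask = (t >= post_window[0]) & (t <= post_window[1])
    if pre_mask.sum() < 5 or post_mask.sum() < 5:
        raise ValueError("each baseline window needs >= 5 points")
    peak_i = int(np.argmax(cp))
    # a transition is present when the maximum clearly exceeds the scan
    # edges (fixed 10% margins, independent of the user windows)
    edge = 0.10 * (t[-1] - t[0])
    edge_mask = (t <= t[0] + edge) | (t >= t[-1] - edge)
    edge_level = float(np.abs(cp[edge_mask]).max())
    has_peak = cp[peak_i] > edge_level + 1e-12 * max(1.0, edge_level)
    if has_peak and (pre_window[1] >= t[peak_i] or post_window[0] <= t[peak_i]):
        raise ValueError("baseline windows must not overlap the transition peak")

    corrected = cp.copy()
    for _ in range(max(1, n_iter)):
        pre_fit = np.polyfit(t[pre_mask], corrected[pre_mask], 1)
        post_fit = np.polyfit(t[post_mask], corrected[post_mask], 1)
        # progress = normalized running integral of the signal above the
        # current pre-transition line
        signal = corrected - np.polyval(pre_fit, t)
        area = np.concatenate([[0.0], np.cumsum(
            0.5 * (signal[1:] + signal[:-1]) * np.diff(t))])
        total = area[-1]
        alpha = area / total if total != 0 else np.zeros_like(area)
        alpha = np.clip(alpha, 0.0, 1.0)
        baseline = (1.0 - alpha) * np.polyval(pre_fit, t) \
            + alpha * np.polyval(post_fit, t)
        corrected = corrected - baseline
    return Thermogram(t, corrected, raw.protein_molar, raw.scan_rate_k_min)


def integrate_enthalpy(t: Thermogram) -> float:
    """Calorimetric enthalpy: trapezoidal area under Cp_exc(T), kJ/mol."""
    return float(np.trapezoid(t.cp_exc, t.temperature_k))


def find_td(t: Thermogram, warn_multimodal: bool = True) -> float:
    """Denaturation temperature: Cp_exc maximum, quadratic-refined.

    A local parabola through the three grid points around the maximum
    sharpens the estimate below the grid step.  Additional local maxima
    comparable to the global one (shouldered thermograms) trigger a
    warning and the lowest-temperature dominant maximum is returned.
    """
    temp, cp = t.temperature_k, t.cp_exc
    if temp.size < 3:
        raise ValueError("thermogram too short to locate a peak")
    peak = float(np.max(cp))
    # candidate maxima: interior points above both neighbours and >= 95% peak
    interior = np.arange(1, temp.size - 1)
    is_max = (cp[interior] >= cp[interior - 1]) & (cp[interior] >= cp[interior + 1])
    cands = interior[is_max & (cp[interior] >= 0.95 * peak)]
    if cands.size == 0:
        cands = np.array([int(np.argmax(cp))])
    # merge plateau-adjacent candidates
    distinct = [cands[0]]
    for i in cands[1:]:
        if i - distinct[-1] > 2:
            distinct.append(i)
    if len(distinct) > 1 and warn_multimodal:
        warnings.warn("multiple comparable maxima: shouldered thermogram?",
                      stacklevel=2)
    i = int(distinct[0])
    if i == 0 or i == temp.size - 1:
        return float(temp[i])
    x0, x1, x2 = temp[i - 1: i + 2]
    y0, y1, y2 = cp[i - 1: i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return float(x1)
    return float(-b / (2 * a))


def fit_two_state(
    t: Thermogram,
    fit_dcp: bool = False,
    fail_residual_frac: float = FAIL_RESIDUAL_FRAC,
) -> TwoStateParams:
    """Levenberg-Marquardt fit of the two-state Cp_exc model.

    Starts from find_td / integrate_enthalpy, fits (dH_vH, T_d) — and
    dCp when requested — and reports the cooperativity ratio
    dH_vH/dH_cal plus the RMS residual.  Status is "FAILED" when the
    RMS residual exceeds `fail_residual_frac` of the peak height, the
    signature of multi-population (non-two-state) thermograms.
    """
    temp, cp = t.temperature_k, t.cp_exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        td0 = find_td(t, warn_multimodal=False)
    dh0 = integrate_enthalpy(t)
    if dh0 <= 0:
        raise ValueError("non-positive integrated enthalpy: not an endotherm")
    peak_height = float(np.max(cp))

    params = lmfit.Parameters()
    params.add("dh_vh", value=dh0, min=1.0)
    params.add("t_d", value=td0, min=temp[0], max=temp[-1])
    params.add("dcp", value=0.0, vary=fit_dcp)

    def resid(p):
        return cp - two_state_cp(temp, p["dh_vh"].value, p["t_d"].value,
                                 p["dcp"].value)

    out = lmfit.minimize(resid, params, method="leastsq")
    dh_vh = float(out.params["dh_vh"].value)
    td = float(out.params["t_d"].value)
    dcp = float(out.params["dcp"].value)
    rms = float(np.sqrt(np.mean(out.residual ** 2)))
    status = "OK"
    flags: list[str] = []
    if not out.success:
        status = "FAILED"
        flags.append("optimizer did not converge")
    if rms > fail_residual_frac * peak_height:
        status = "FAILED"
        flags.append(
            f"RMS residual {rms:.3g} exceeds {fail_residual_frac:.0%} of peak "
            f"height {peak_height:.3g}: not two-state"
        )
    return TwoStateParams(
        t_d_k=td, dh_cal=dh0, dh_vh=dh_vh, dcp=dcp,
        ds_at_td=dh0 / td,
        cooperativity_ratio=dh_vh / dh0 if dh0 else math.nan,
        rms_residual=rms, peak_height=peak_height,
        status=status, flags=flags,
    )


def entropy_at_td(params: TwoStateParams, use_vh: bool = False) -> float:
    """Denaturation entropy dS = dH / T_d (dG = 0 at the midpoint), kJ/mol/K."""
    if params.t_d_k <= 0:
        raise ValueError("T_d must be positive")
    dh = params.dh_vh if use_vh else params.dh_cal
    return dh / params.t_d_k


def correct_native_loss(t: Thermogram, loss_fraction) -> Thermogram:
    """Rescale a thermogram for loss of native protein during incubation.

    `loss_fraction` is a single fraction in [0, 1) or a sequence of
    sequential fractions (e.g. (0.12, 0.09) for a 12% loss over the
    first day followed by a further 9%), composed multiplicatively:
    Cp_exc is divided by prod(1 - loss_i).
    """
    losses = np.atleast_1d(np.asarray(loss_fraction, dtype=float))
    if np.any(losses < 0) or np.any(losses >= 1):
        raise ValueError("each loss fraction must satisfy 0 <= loss < 1")
    surviving = float(np.prod(1.0 - losses))
    return Thermogram(t.temperature_k, t.cp_exc / surviving,
                      t.protein_molar, t.scan_rate_k_min)
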