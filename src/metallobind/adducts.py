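"""Intact-protein ESI-MS adduct mass bookkeeping and envelope deconvolution.

When a cationic metal fragment (e.g. [Pt(phenylterpyridine)]2+ left after
loss of the labile halide) binds a protein, the deconvolved neutral mass
shifts by the fragment's average mass minus one hydrogen atom per unit of
fragment charge — covalent/ionic binding of a q+ fragment displaces q
protons from the protein to keep the species neutral:

    M(k adducts) = M0 + k * (m_fragment - q * m_H)

Small-anion artefacts (the classic isobaric +98 Da sulphuric/phosphoric
acid adducts carried over from protein purification) are treated as
neutral additions.  The assignment engine matches an observed neutral
peak list against all compositions (k fragments, optional small adduct)
within a mass tolerance, flagging isobaric ambiguities instead of
silently choosing.

A minimal charge-envelope deconvolver is included for synthetic,
centroided positive-mode spectra: candidate neutral masses on a grid are
scored by the summed intensity of raw peaks falling within an m/z
tolerance of (M + z m_p)/z across the charge range, and each accepted
candidate is refined by the intensity-weighted mean of the matched
peaks' implied masses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .formula import Formula, HYDROGEN_MASS, PROTON_MASS, average_mass, parse_formula

__all__ = [
    "FragmentSpec",
    "NeutralPeakList",
    "AdductAssignment",
    "DEFAULT_SMALL_ADDUCTS",
    "predict_adduct_mass",
    "assign_adducts",
    "mz_from_mass",
    "deconvolve_envelope",
]

#: Isobaric purification-artefact adducts proposed by default (+98 Da).
DEFAULT_SMALL_ADDUCTS: tuple = ("H3PO4", "H2SO4")


@dataclass(frozen=True)
class FragmentSpec:
    """A metal fragment that binds the protein, displacing `charge` protons.

    `charge` is the fragment's formal positive charge (0-2): on binding,
    that many protein protons are displaced so the adduct stays neutral.
    """

    label: str
    formula: Formula
    charge: int = 2
    note: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", parse_formula(self.formula))
        if self.charge not in (0, 1, 2):
            raise ValueError("fragment charge must be 0, 1 or 2")

    @property
    def mass_shift(self) -> float:
        """Neutral-mass increment per bound fragment, Da."""
        return average_mass(self.formula) - self.charge * HYDROGEN_MASS


@dataclass(frozen=True)
class NeutralPeakList:
    """Deconvolved neutral-mass peaks with an assignment tolerance."""

    masses_da: np.ndarray
    intensities: np.ndarray
    tolerance_da: float = 1.5

    def __post_init__(self) -> None:
        m = np.asarray(self.masses_da, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if m.shape != i.shape or m.ndim != 1:
            raise ValueError("masses and intensities must be equal-length 1-D arrays")
        if m.size and np.any(m <= 0):
            raise ValueError("neutral masses must be positive")
        if self.tolerance_da <= 0:
            raise ValueError("tolerance must be positive")
        object.__setattr__(self, "masses_da", m)
        object.__setattr__(self, "intensities", i)


@dataclass
class AdductAssignment:
    """One observed peak matched to a protein + k*fragment (+anion) composition."""

    observed_da: float
    predicted_da: float
    k: int
    fragment: Optional[FragmentSpec]
    small_adduct: Optional[str]
    error_da: float
    intensity: float = 0.0
    ambiguous_with: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def composition(self) -> str:
        parts = ["P"]
        if self.k:
            parts.append(f"{self.k}x[{self.fragment.label}]")
        if self.small_adduct:
            parts.append(self.small_adduct)
        return " + ".join(parts)


def predict_adduct_mass(m0: float, frag: FragmentSpec, k: int = 1) -> float:
    """Neutral mass of the protein carrying k fragments (q protons each lost)."""
    if m0 <= 0:
        raise ValueError("free protein mass must be positive")
    if k < 0:
        raise ValueError("stoichiometry k must be non-negative")
    return m0 + k * frag.mass_shift


def assign_adducts(
    peaks: NeutralPeakList,
    m0: float,
    fragments: Sequence[FragmentSpec],
    k_max: int = 2,
    small_adducts: Sequence = DEFAULT_SMALL_ADDUCTS,
) -> List[AdductAssignment]:
    """Match each neutral peak to its best protein/fragment/anion composition.

    Candidate compositions enumerate k in [0, k_max] for each fragment
    times {no small adduct} + `small_adducts`; the composition with the
    smallest |observed - predicted| within `peaks.tolerance_da` wins.
    When two candidates both lie within tolerance and within 0.5 Da of
    one another the peak is flagged ambiguous and both are reported
    (the isobaric sulphate/phosphate case).  Unmatched peaks get an
    "unassigned" flag.
    """
    small: list = [None] + [
        a if isinstance(a, (Formula, str)) else a for a in small_adducts
    ]
    # candidate list: (predicted mass, k, fragment, adduct-name)
    candidates = []
    frag_choices = [(0, None)] + [
        (k, f) for f in fragments for k in range(1, k_max + 1)
    ]
    for (k, frag), adduct in itertools.product(frag_choices, small):
        mass = m0 + (k * frag.mass_shift if frag else 0.0)
        name = None
        if adduct is not None:
            name = str(adduct)
            mass += average_mass(adduct)
        candidates.append((mass, k, frag, name))

    out: List[AdductAssignment] = []
    for obs, inten in zip(peaks.masses_da, peaks.intensities):
        within = [
            (abs(obs - mass), mass, k, frag, name)
            for mass, k, frag, name in candidates
            if abs(obs - mass) <= peaks.tolerance_da
        ]
        if not within:
            out.append(AdductAssignment(
                observed_da=float(obs), predicted_da=float("nan"), k=0,
                fragment=None, small_adduct=None, error_da=float("nan"),
                intensity=float(inten), flags=["unassigned"],
            ))
            continue
        within.sort(key=lambda c: c[0])
        err, mass, k, frag, name = within[0]
        rivals = [
            c for c in within[1:] if abs(c[1] - mass) <= 0.5
        ]
        asg = AdductAssignment(
            observed_da=float(obs), predicted_da=float(mass), k=int(k),
            fragment=frag, small_adduct=name,
            error_da=float(obs - mass), intensity=float(inten),
        )
        if rivals:
            asg.flags.append("isobaric-ambiguity")
            for _, rmass, rk, rfrag, rname in rivals:
                rival = AdductAssignment(
                    observed_da=float(obs), predicted_da=float(rmass),
                    k=int(rk), fragment=rfrag, small_adduct=rname,
                    error_da=float(obs - rmass), intensity=float(inten),
                )
                asg.ambiguous_with.append(rival)
        out.append(asg)
    return out


def mz_from_mass(m: float, z: int) -> float:
    """Positive-mode m/z of an [M + zH]z+ ion: (M + z m_p)/z."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    return (m + z * PROTON_MASS) / z


def deconvolve_envelope(
    raw: Sequence,
    z_range: Sequence[int] = range(8, 15),
    mass_grid_step: float = 0.25,
    mz_tol: float = 0.75,
    rel_threshold: float = 0.05,
    min_charge_states: int = 3,
) -> NeutralPeakList:
    """Recover neutral masses from a centroided multi-charge envelope.

    Scores each candidate mass M on a uniform grid by the summed
    intensity of raw peaks within `mz_tol` of (M + z m_p)/z over
    `z_range`; candidates must match at least `min_charge_states`
    distinct charges and exceed `rel_threshold` of the best score.
    Contiguous above-threshold grid regions are collapsed to one
    species each, refined by the intensity-weighted mean of the matched
    peaks' implied masses z*(m/z) - z*m_p.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return NeutralPeakList(np.array([]), np.array([]))
    mz, inten = raw[:, 0], raw[:, 1]
    z_range = sorted(set(int(z) for z in z_range))
    if not z_range or z_range[0] < 1:
        raise ValueError("z_range must contain positive charges")

    implied = np.concatenate([z * mz - z * PROTON_MASS for z in z_range])
    lo, hi = implied.min(), implied.max()
    grid = np.arange(lo, hi + mass_grid_step, mass_grid_step)
    score = np.zeros_like(grid)
    n_z = np.zeros_like(grid, dtype=int)
    for z in z_range:
        pred = (grid + z * PROTON_MASS) / z
        # nearest raw peak per grid mass
        order = np.argsort(mz)
        mz_s, in_s = mz[order], inten[order]
        idx = np.clip(np.searchsorted(mz_s, pred), 1, mz_s.size - 1)
        left, right = mz_s[idx - 1], mz_s[np.minimum(idx, mz_s.size - 1)]
        use_left = np.abs(pred - left) <= np.abs(pred - right)
        nearest = np.where(use_left, idx - 1, idx)
        dist = np.abs(pred - mz_s[nearest])
        hit = dist <= mz_tol
        score += np.where(hit, in_s[nearest], 0.0)
        n_z += hit.astype(int)

    valid = (n_z >= min_charge_states) & (score > 0)
    if not np.any(valid):
        warnings.warn("no candidate neutral mass exceeded the threshold",
                      stacklevel=2)
        return NeutralPeakList(np.array([]), np.array([]))
    threshold = rel_threshold * score[valid].max()
    accept = valid & (score >= threshold)

    # contiguous accepted runs -> one species each
    masses, heights = [], []
    i = 0
    while i < grid.size:
        if not accept[i]:
            i += 1
            continue
        j = i
        while j + 1 < grid.size and accept[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        m_best = grid[seg][np.argmax(score[seg])]
        # refine: intensity-weighted mean of implied masses of matched peaks
        num = den = 0.0
        for z in z_range:
            pred = (m_best + z * PROTON_MASS) / z
            d = np.abs(mz - pred)
            kbest = int(np.argmin(d))
            if d[kbest] <= mz_tol:
                num += inten[kbest] * (z * mz[kbest] - z * PROTON_MASS)
                den += inten[kbest]
        masses.append(num / den if den else float(m_best))
        heights.append(float(score[seg].max()))
        i = j + 1

    order = np.argsort(masses)
    return NeutralPeakList(np.asarray(masses)[order], np.asarray(heights)[order])
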