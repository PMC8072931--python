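"""Molecular formulas and atomic masses for adduct-mass bookkeeping.

Average masses are the working currency here: deconvolved intact-protein
masses from multi-charge ESI envelopes are average-mass-scale quantities,
so metal-fragment and small-anion adduct deltas must be computed on the
same scale.  Monoisotopic masses are carried for completeness.

Atomic weights are the IUPAC 2021 standard atomic weights (conventional
values where IUPAC gives an interval), embedded as data so that every
predicted adduct mass is reproducible bit-for-bit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

__all__ = [
    "AVERAGE_MASS",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "Formula",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
]

#: IUPAC 2021 standard atomic weights (Da); conventional value where IUPAC
#: publishes an interval (H, C, N, O, S, Cl).
AVERAGE_MASS: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.98976928,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Ru": 101.07,
    "Pd": 106.42,
    "I": 126.90447,
    "Pt": 195.084,
    "Au": 196.966570,
}

#: Monoisotopic masses of the most abundant isotope (Da).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Fe": 55.9349375,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "Ru": 101.9043493,
    "Pd": 105.903486,
    "I": 126.904473,
    "Pt": 194.9647911,
    "Au": 196.9665687,
}

#: Mass of the bare proton (Da), used for m/z conversion in positive mode.
PROTON_MASS: float = 1.007276466621

#: Average mass of the hydrogen atom (Da), used for proton-displacement
#: bookkeeping on the average-mass scale.
HYDROGEN_MASS: float = AVERAGE_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition (element symbol -> positive count)."""

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        for symbol, count in counts.items():
            if symbol not in AVERAGE_MASS:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count <= 0:
                raise ValueError(
                    f"count for {symbol} must be a positive integer, got {count!r}"
                )
        object.__setattr__(self, "element_counts", counts)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.element_counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.element_counts)
        for symbol, count in other.element_counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        if k == 0:
            return Formula({})
        return Formula({s: c * k for s, c in self.element_counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.element_counts) == dict(other.element_counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.element_counts.items()))

    def hill_string(self) -> str:
        """Hill-notation string (C first, H second, rest alphabetical)."""
        counts = dict(self.element_counts)
        ordered: list[str] = []
        if "C" in counts:
            ordered.append("C")
            if "H" in counts:
                ordered.append("H")
            ordered.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            ordered.extend(sorted(counts))
        return "".join(
            f"{s}{counts[s]}" if counts[s] > 1 else s for s in ordered
        )

    def __str__(self) -> str:
        return self.hill_string()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string such as ``"C21H15N3Pt"``.

    Symbols are case-sensitive (``Co`` is cobalt, ``CO`` is carbon
    monoxide... would be, were Co in the table).  Repeated symbols
    accumulate.  Unknown symbols and malformed strings raise ValueError.
    """
    if not isinstance(text, str):
        raise TypeError("formula must be a string")
    stripped = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        match = _TOKEN.match(stripped, pos)
        if match is None:
            raise ValueError(
                f"malformed formula {text!r} at position {pos}: "
                f"{stripped[pos:]!r}"
            )
        symbol, digits = match.groups()
        if symbol not in AVERAGE_MASS:
            raise ValueError(f"unknown element symbol {symbol!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise ValueError(f"zero count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return Formula(counts)


def _mass(f: Formula | str, table: Mapping[str, float]) -> float:
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(count * table[symbol] for symbol, count in f)


def average_mass(f: Formula | str) -> float:
    """Average (standard-atomic-weight) mass of a formula, in Da."""
    return _mass(f, AVERAGE_MASS)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass of a formula, in Da."""
    return _mass(f, MONOISOTOPIC_MASS)
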