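"""Molecular-formula algebra, monoisotopic masses, ion m/z and isotope patterns.

This is the numeric kernel of the suspect-screening pipeline: every mass,
m/z and ppm error elsewhere in the package is computed here, from a fixed
internal table of monoisotopic atomic masses.  The table is deliberately not
user-editable so that printed-value comparisons are stable across runs.

Conventions
-----------
* Ion m/z includes the electron mass: for the deprotonated ion
  ``[M-H]- = M - m(H) + m(e)``; for the protonated ion
  ``[M+H]+ = M + m(H) - m(e)``.
* ppm error is signed as ``(theoretical - observed) / theoretical * 1e6``.
* Isotope patterns are coarse: peaks are aggregated by nominal mass offset
  (M, M+1, M+2, ...), not resolved into fine structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

__all__ = [
    "MolecularFormula",
    "IonSpecies",
    "IsotopePattern",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "isotope_pattern",
    "pattern_score",
    "M_H_NEG",
    "M_H_POS",
    "ELECTRON_MASS",
]

#: Monoisotopic atomic masses, Da (lightest stable isotope).
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

ELECTRON_MASS: float = 0.00054858

#: Natural isotope composition per element: (mass, abundance) per isotope,
#: nominal-mass-ordered.  Abundances sum to 1 per element.
ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335484, 0.0107)],
    "H": [(1.00782503, 0.999885), (2.01410178, 0.000115)],
    "N": [(14.00307401, 0.99636), (15.00010890, 0.00364)],
    "O": [(15.99491462, 0.99757), (16.99913176, 0.00038), (17.99915961, 0.00205)],
    "S": [
        (31.97207117, 0.9499),
        (32.97145891, 0.0075),
        (33.96786701, 0.0425),
        (35.96708070, 0.0001),
    ],
}


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: element symbol -> non-negative count.

    Supports addition and subtraction (subtraction raises
    :class:`FormulaError` if any count would go negative, signalling a
    chemically impossible operation).
    """

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Dict[str, int] | Iterable[Tuple[str, int]]):
        items = dict(counts)
        for el, n in items.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"bad count for {el}: {n!r}")
        items = {el: int(n) for el, n in items.items() if n > 0}
        if not items:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(
            self, "counts", tuple(sorted(items.items()))
        )

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"cannot remove {n} {el} from {self}: negative count"
                )
        return MolecularFormula(merged)

    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        d = self.as_dict()
        order = [e for e in ("C", "H") if e in d] + sorted(
            e for e in d if e not in ("C", "H")
        )
        return "".join(f"{e}{d[e]}" if d[e] != 1 else e for e in order)


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ±H adduct ion.

    ``adduct`` is ``"[M-H]-"`` (deprotonated, negative mode) or
    ``"[M+H]+"`` (protonated, positive mode).
    """

    adduct: str

    def __post_init__(self):
        if self.adduct not in ("[M-H]-", "[M+H]+"):
            raise ValueError(f"unsupported adduct {self.adduct!r}")

    @property
    def polarity(self) -> str:
        return "negative" if self.adduct == "[M-H]-" else "positive"


M_H_NEG = IonSpecies("[M-H]-")
M_H_POS = IonSpecies("[M+H]+")


@dataclass(frozen=True)
class IsotopePattern:
    """Coarse isotope pattern: (nominal offset, exact m/z, relative abundance).

    Abundances are relative to the base (most abundant) peak, which has
    abundance 1.  Offsets are strictly increasing.
    """

    peaks: Tuple[Tuple[int, float, float], ...]

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        offsets = [p[0] for p in self.peaks]
        if offsets != sorted(set(offsets)):
            raise ValueError("offsets must be strictly increasing")
        abunds = [p[2] for p in self.peaks]
        if not np.isclose(max(abunds), 1.0):
            raise ValueError("base peak abundance must be 1")
        if any(a <= 0 or a > 1 + 1e-12 for a in abunds):
            raise ValueError("abundances must lie in (0, 1]")

    def abundance_at(self, offset: int) -> float:
        for o, _, a in self.peaks:
            if o == offset:
                return a
        return 0.0


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a plain formula string such as ``"C10H16"`` or ``"H2O"``.

    No parentheses, charges or isotope labels; repeated element symbols
    accumulate.  Raises :class:`FormulaError` on anything unrecognised.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {el!r} in {text!r}")
        if num == "0":
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic (lightest-isotope) mass in Da."""
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts)


def ion_mz(f: MolecularFormula, ion: IonSpecies = M_H_NEG) -> float:
    """Theoretical m/z of the ±H adduct of neutral ``f``, electron included."""
    m = monoisotopic_mass(f)
    if ion.adduct == "[M-H]-":
        if f["H"] < 1:
            raise FormulaError(f"cannot deprotonate H-free formula {f}")
        return m - ATOMIC_MASS["H"] + ELECTRON_MASS
    return m + ATOMIC_MASS["H"] - ELECTRON_MASS


def anion_mz(f: MolecularFormula) -> float:
    """m/z of an anion given directly by its *ionic* formula (adds one electron)."""
    return monoisotopic_mass(f) + ELECTRON_MASS


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed mass error in ppm: ``(theoretical - observed)/theoretical * 1e6``."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (theoretical - observed) / theoretical * 1e6


def _element_offset_dist(el: str) -> List[Tuple[int, float, float]]:
    base = ISOTOPES[el][0][0]
    out = []
    for mass, ab in ISOTOPES[el]:
        out.append((int(round(mass - base)), ab, mass))
    return out


def isotope_pattern(
    f: MolecularFormula, max_offset: int = 3, prune: float = 1e-4
) -> IsotopePattern:
    """Coarse isotope pattern of ``f`` by convolution over nominal-mass offsets.

    For each element the per-atom isotope distribution is collapsed onto
    integer nominal-mass offsets and self-convolved ``count`` times; element
    distributions are then convolved together.  The exact m/z of each
    aggregated peak is the abundance-weighted mean mass within the offset.
    Peaks with relative abundance below ``prune`` (fraction of the base
    peak) are dropped.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    if not 0 <= prune < 1:
        raise ValueError("prune must be in [0, 1)")
    size = max_offset + 1
    # prob[k]: probability of total offset k; msum[k]: prob-weighted mass.
    prob = np.zeros(size)
    prob[0] = 1.0
    msum = np.zeros(size)
    for el, n in f.counts:
        dist = _element_offset_dist(el)
        ep = np.zeros(size)
        em = np.zeros(size)
        for off, ab, mass in dist:
            if off < size:
                ep[off] += ab
                em[off] += ab * mass
        for _ in range(n):
            new_p = np.zeros(size)
            new_m = np.zeros(size)
            for k in range(size):
                if ep[k] == 0 and em[k] == 0:
                    continue
                new_p[k:] += prob[: size - k] * ep[k]
                new_m[k:] += msum[: size - k] * ep[k] + prob[: size - k] * em[k]
            prob, msum = new_p, new_m
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mass = np.where(prob > 0, msum / np.maximum(prob, 1e-300), 0.0)
    base = prob.max()
    peaks = []
    for k in range(size):
        if prob[k] > 0 and prob[k] / base >= max(prune, 1e-300):
            peaks.append((k, float(mean_mass[k]), float(prob[k] / base)))
    if prune > 0:
        peaks = [p for p in peaks if p[2] >= prune]
    return IsotopePattern(tuple(peaks))


def isotope_probabilities(f: MolecularFormula, max_offset: int) -> np.ndarray:
    """Absolute (unnormalised) offset probabilities, for conservation checks."""
    pat_size = max_offset + 1
    prob = np.zeros(pat_size)
    prob[0] = 1.0
    for el, n in f.counts:
        ep = np.zeros(pat_size)
        for off, ab, _ in _element_offset_dist(el):
            if off < pat_size:
                ep[off] += ab
        for _ in range(n):
            prob = np.convolve(prob, ep)[:pat_size]
    return prob


def pattern_score(observed: IsotopePattern, theoretical: IsotopePattern) -> float:
    """Agreement score in [0, 1] between two coarse patterns.

    ``1 - mean(|a_obs - a_theo|)`` over the union of offsets (a peak absent
    from one pattern contributes abundance 0), floored at 0.  Identical
    patterns score 1; the score is symmetric for aligned offsets.
    """
    offsets = sorted(
        {p[0] for p in observed.peaks} | {p[0] for p in theoretical.peaks}
    )
    devs = [
        abs(observed.abundance_at(o) - theoretical.abundance_at(o)) for o in offsets
    ]
    return max(0.0, 1.0 - float(np.mean(devs)))
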