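"""Elemental-formula arithmetic for small-molecule mass spectrometry.

Monoisotopic masses, proton-adduct and ferric-complex ion math, ring and
double-bond equivalents, and brute-force molecular-formula decomposition
under a ppm tolerance.  All masses are in Da; ppm errors are defined as
``1e6 * (observed - theoretical) / theoretical``.

Charge handling is proton-adduct arithmetic only: the screen analyses
singly protonated MH+ species.  The electron mass is kept in
:class:`MassConstants` for cation-radical extensions but is ignored for
[M+H]+ (error below 1 ppm above m/z 100).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "ElementalFormula",
    "MassConstants",
    "MASS",
    "DecompositionCandidate",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "neutral_from_protonated",
    "ferric_complex_mz",
    "FE_MINUS_3H",
    "FE54_FE56_SPACING",
    "CH2_MASS",
    "O_MASS",
    "rdbe",
    "decompose_mass",
    "ppm_error",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element counts."""


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic masses (Da) and isotope abundances.

    Atomic masses from the AME2020 atomic-mass evaluation / NIST isotope
    tables, kept to >= 6 decimals so that all derived ion masses are good
    to well below 0.1 mDa.
    """

    atomic: Mapping[str, float] = field(
        default_factory=lambda: {
            "C": 12.0,
            "H": 1.00782503207,
            "N": 14.0030740048,
            "O": 15.9949146196,
            "S": 31.9720710015,
            # iron enters ions via the ferric-complex substitution only
            "Fe": 55.9349363,
        }
    )
    proton: float = 1.007276466621
    electron: float = 0.000548579909
    fe54: float = 53.9396090
    fe56: float = 55.9349363
    # fractional natural abundances
    fe54_abundance: float = 0.05845
    fe56_abundance: float = 0.91754
    c13_abundance: float = 0.0107

    @property
    def fe_spacing(self) -> float:
        """m/z gap between the 56Fe and 54Fe isotopologues (~1.99533 Da)."""
        return self.fe56 - self.fe54

    @property
    def fe_ratio(self) -> float:
        """Natural 54Fe/56Fe abundance ratio (~0.0637)."""
        return self.fe54_abundance / self.fe56_abundance


MASS = MassConstants()

#: m/z offset between the ferric-complex ion [M - 3H + Fe + H]+ and the
#: apo ion [M + H]+ of the same neutral M: mass(56Fe) - 3 * mass(H).
FE_MINUS_3H = MASS.fe56 - 3.0 * MASS.atomic["H"]

#: 56Fe - 54Fe isotopologue spacing.
FE54_FE56_SPACING = MASS.fe_spacing

CH2_MASS = MASS.atomic["C"] + 2.0 * MASS.atomic["H"]
O_MASS = MASS.atomic["O"]

# Hill order: C first, H second, remaining elements alphabetical.
_HILL_ORDER = ("C", "H")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: element symbol -> non-negative count.

    Equality is element-wise; zero counts are dropped on construction so
    ``CH4O0`` never arises.  The element alphabet is whatever
    :data:`MASS` knows about (CHNOS plus Fe by default).
    """

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[Tuple[str, int]]):
        items = dict(counts)
        for el, n in items.items():
            if el not in MASS.atomic:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
        cleaned = tuple(sorted((el, n) for el, n in items.items() if n > 0))
        object.__setattr__(self, "counts", cleaned)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def get(self, element: str, default: int = 0) -> int:
        return self.as_dict().get(element, default)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        return format_formula(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C6H10O2"``.

    An omitted count means 1.  Explicit zero counts, unknown symbols and
    leftover characters (e.g. ``"C-3H"``) raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in MASS.atomic:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def format_formula(f: ElementalFormula) -> str:
    """Hill-notation string: C, H, then the rest alphabetically."""
    d = f.as_dict()
    parts: List[str] = []
    for el in _HILL_ORDER:
        if el in d:
            n = d.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(d):
        n = d[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    return sum(n * MASS.atomic[el] for el, n in f.counts)


def ppm_error(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical


def protonated_mz(neutral_mass: float) -> float:
    """m/z of the singly protonated ion [M+H]+ for a neutral mass in Da."""
    if neutral_mass < 0:
        raise ValueError(f"neutral mass must be non-negative, got {neutral_mass}")
    return neutral_mass + MASS.proton


def neutral_from_protonated(mz: float) -> float:
    """Neutral monoisotopic mass of the M in an observed [M+H]+ ion."""
    return mz - MASS.proton


def ferric_complex_mz(apo_neutral_mass: float) -> float:
    """m/z of the protonated ferric complex [M - 3H + Fe + H]+.

    The neutral holo species is the tris-deprotonated ferric complex: the
    three hydroxamate protons are replaced by one Fe(III).  Its protonated
    ion therefore sits ``mass(56Fe) - 3 * mass(H) = 52.91146`` Da above the
    apo [M+H]+ ion, independent of M.
    """
    three_h = 3.0 * MASS.atomic["H"]
    if apo_neutral_mass <= three_h:
        raise ValueError(
            f"apo neutral mass {apo_neutral_mass} too small to lose three protons"
        )
    return apo_neutral_mass - three_h + MASS.fe56 + MASS.proton


def rdbe(f: ElementalFormula) -> float:
    """Ring and double-bond equivalents, (2C + 2 + N - H) / 2.

    O and S are divalent and do not contribute.
    """
    d = f.as_dict()
    return (2.0 * d.get("C", 0) + 2.0 + d.get("N", 0) - d.get("H", 0)) / 2.0


#: Default per-element count bounds for decomposition; generous enough for
#: metabolites up to ~1 kDa without exploding the search space.
DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 120),
    "N": (0, 15),
    "O": (0, 25),
    "S": (0, 5),
}

DEFAULT_RDBE_RANGE: Tuple[float, float] = (0.0, 40.0)


@dataclass(frozen=True)
class DecompositionCandidate:
    """A formula consistent with a measured neutral mass."""

    formula: ElementalFormula
    mass_error_ppm: float
    rdbe: float


def decompose_mass(
    neutral_mass: float,
    tol_ppm: float = 5.0,
    bounds: Optional[Mapping[str, Tuple[int, int]]] = None,
    rdbe_range: Tuple[float, float] = DEFAULT_RDBE_RANGE,
    hc_ratio_range: Optional[Tuple[float, float]] = None,
) -> List[DecompositionCandidate]:
    """Enumerate CHNOS formulas matching a neutral mass within ``tol_ppm``.

    Exhaustive over the per-element ``bounds`` (default CHNOS,
    C<=60/H<=120/N<=15/O<=25/S<=5): all heavy-element counts are iterated
    and the hydrogen count solved from the mass residual, which is
    equivalent to the full nested enumeration but linear in the product of
    heavy-element ranges.  Results are sorted by absolute ppm error, ties
    broken by Hill-notation string, so the order is deterministic.

    ``hc_ratio_range`` optionally restricts H/C (off by default).
    An empty list (no candidate within tolerance) is not an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    for el in b:
        if el not in MASS.atomic:
            raise FormulaError(f"unknown element in bounds: {el!r}")
    h_lo, h_hi = b.pop("H", (0, 0))
    heavy = sorted(b.items())  # deterministic iteration order
    tol_da = tol_ppm * 1e-6 * neutral_mass
    m_h = MASS.atomic["H"]

    out: List[DecompositionCandidate] = []

    def recurse(idx: int, acc_mass: float, acc: Dict[str, int]) -> None:
        if acc_mass > neutral_mass + tol_da:
            return
        if idx == len(heavy):
            resid = neutral_mass - acc_mass
            if resid + tol_da < 0:
                return
            n_min = max(h_lo, math.ceil((resid - tol_da) / m_h))
            n_max = min(h_hi, math.floor((resid + tol_da) / m_h))
            for n_h in range(n_min, n_max + 1):
                mass = acc_mass + n_h * m_h
                if abs(mass - neutral_mass) > tol_da:
                    continue
                counts = {el: c for el, c in acc.items() if c > 0}
                if n_h:
                    counts["H"] = n_h
                if not counts:
                    continue
                f = ElementalFormula(counts)
                r = rdbe(f)
                if not (rdbe_range[0] <= r <= rdbe_range[1]):
                    continue
                if hc_ratio_range is not None:
                    n_c = counts.get("C", 0)
                    if n_c == 0:
                        continue
                    ratio = n_h / n_c
                    if not (hc_ratio_range[0] <= ratio <= hc_ratio_range[1]):
                        continue
                out.append(
                    DecompositionCandidate(
                        formula=f,
                        mass_error_ppm=ppm_error(neutral_mass, mass),
                        rdbe=r,
                    )
                )
            return
        el, (lo, hi) = heavy[idx]
        m_el = MASS.atomic[el]
        for n in range(lo, hi + 1):
            new_mass = acc_mass + n * m_el
            if new_mass > neutral_mass + tol_da:
                break
            acc[el] = n
            recurse(idx + 1, new_mass, acc)
        acc.pop(el, None)

    recurse(0, 0.0, {})
    out.sort(key=lambda c: (abs(c.mass_error_ppm), c.formula.hill()))
    return out
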