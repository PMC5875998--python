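"""Exact-mass arithmetic: formulas, adduct m/z, ppm errors, isotope patterns.

This module is the numerical foundation of the toolkit. An
:class:`ElementalFormula` is an immutable element→count map; everything else
(monoisotopic mass, adduct m/z, ring-double-bond equivalents, aggregated
isotope envelopes) derives from it and the pinned isotope table in
:mod:`hybridrank.elements`.

Conventions
-----------
* Monoisotopic mass sums the mass of each element's *most abundant* isotope.
* Protonation adds/removes a bare proton (1.00727646 Da), not an H atom.
* ppm error = (observed − theoretical) / theoretical × 1e6, signed;
  :func:`truncated_abs_ppm` floors the absolute value to an integer, the
  convention under which reported Q-TOF mass accuracies are stated here.
* Isotope patterns are aggregated at nominal-mass resolution (M, M+1, M+2…),
  each aggregate carrying the abundance-weighted mean mass; fine structure
  within a nominal-mass peak is not resolved.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .elements import HALOGENS, ISOTOPES, MONOISOTOPIC, PROTON_MASS, VALENCE

__all__ = [
    "ElementalFormula",
    "Adduct",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "truncated_abs_ppm",
    "rdbe",
    "isotope_pattern",
    "ADDUCTS",
    "get_adduct",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → count map with Hill-order canonical formatting.

    Counts must be non-negative with at least one positive entry, and every
    symbol must exist in the bundled atomic-mass table.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n}
        for el, n in clean.items():
            if el not in MONOISOTOPIC:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def contains(self, other: "ElementalFormula") -> bool:
        """True if ``other`` is an element-wise sub-formula of ``self``."""
        return all(self[el] >= n for el, n in other.counts.items())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-notation string: C, H, then other elements A→Z."""
        parts = []
        rest = dict(self.counts)
        if "C" in rest:
            for el in ("C", "H"):
                if el in rest:
                    n = rest.pop(el)
                    parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(rest):
            n = rest[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation-like formula string, e.g. ``"C5H11NO2"``.

    Multi-digit counts and repeated element symbols (summed) are accepted.
    Raises :class:`FormulaError` on empty input or unknown symbols.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da (most-abundant-isotope convention)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class Adduct:
    """An ionized form such as ``[M+H]+``: mass shift, charge, polarity."""

    name: str
    delta_mass: float
    charge: int
    polarity: str

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(f"charge sign inconsistent with polarity for {self.name}")
        if not math.isfinite(self.delta_mass):
            raise ValueError("adduct delta_mass must be finite")


#: common single-charge adducts keyed by conventional name
ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", PROTON_MASS, 1, "positive"),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1, "negative"),
    "[M+Na]+": Adduct("[M+Na]+", MONOISOTOPIC["Na"] - 0.00054858, 1, "positive"),
    "[M+NH4]+": Adduct(
        "[M+NH4]+",
        MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"] + PROTON_MASS,
        1,
        "positive",
    ),
    "[M+Cl]-": Adduct("[M+Cl]-", MONOISOTOPIC["Cl"] + 0.00054858, -1, "negative"),
}


def get_adduct(name: str) -> Adduct:
    """Look up an adduct by name, accepting the Unicode minus sign."""
    key = name.replace("−", "-").replace(" ", "")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; known: {', '.join(sorted(ADDUCTS))}"
        ) from None


def adduct_mz(f: ElementalFormula | str, a: Adduct | str) -> float:
    """Theoretical m/z of neutral formula ``f`` observed as adduct ``a``."""
    if isinstance(a, str):
        a = get_adduct(a)
    return (monoisotopic_mass(f) + a.delta_mass) / abs(a.charge)


def neutral_mass_from_mz(mz: float, a: Adduct | str) -> float:
    """Invert :func:`adduct_mz`: recover the neutral monoisotopic mass."""
    if isinstance(a, str):
        a = get_adduct(a)
    return mz * abs(a.charge) - a.delta_mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def truncated_abs_ppm(observed: float, theoretical: float) -> int:
    """Floor of the absolute ppm error (integer-ppm reporting convention)."""
    return math.floor(abs(ppm_error(observed, theoretical)))


def rdbe(f: ElementalFormula | str) -> float:
    """Ring-plus-double-bond equivalents.

    General valence form 1 + Σ nᵢ(vᵢ − 2)/2, which for CHNOPS-halogen
    formulas reduces to C + 1 + (N − H − halogens)/2; O and S contribute 0.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    total = 1.0
    for el, n in f.counts.items():
        v = VALENCE.get(el)
        if v is None:
            raise FormulaError(f"no valence defined for element {el}")
        total += n * (v - 2) / 2.0
    return total


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-mass aggregated isotopologue distribution, base peak = 1.

    ``isotopologues`` is an ordered list of ``(mass, abundance)`` with
    strictly increasing masses and the largest abundance normalized to 1.
    """

    isotopologues: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.isotopologues:
            raise ValueError("isotope pattern must have at least one isotopologue")
        masses = [m for m, _ in self.isotopologues]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("isotopologue masses must be strictly increasing")
        abunds = [a for _, a in self.isotopologues]
        if any(a <= 0 or a > 1 + 1e-9 for a in abunds):
            raise ValueError("abundances must lie in (0, 1]")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "IsotopePattern":
        """Normalize arbitrary (mass, abundance) pairs to base peak = 1."""
        pairs = sorted(pairs)
        top = max(a for _, a in pairs)
        if top <= 0:
            raise ValueError("pattern has no positive abundance")
        return cls(tuple((m, a / top) for m, a in pairs if a / top > 0))

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.isotopologues)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.isotopologues)


# (abundance, abundance-weighted mass) accumulators indexed by nominal shift
_Dist = list[tuple[float, float]]


def _element_dist(el: str) -> _Dist:
    isos = ISOTOPES.get(el)
    if isos is None:
        raise FormulaError(f"no isotope data for element {el}")
    base_nominal = round(min(m for m, _ in isos))
    size = max(round(m) - base_nominal for m, _ in isos) + 1
    out: _Dist = [(0.0, 0.0)] * size
    for m, a in isos:
        k = round(m) - base_nominal
        pa, pm = out[k]
        out[k] = (pa + a, pm + a * m)
    return out


def _convolve(x: _Dist, y: _Dist, cutoff: float = 1e-12) -> _Dist:
    out: _Dist = [(0.0, 0.0)] * (len(x) + len(y) - 1)
    for i, (ax, mx) in enumerate(x):
        if ax == 0.0:
            continue
        mean_x = mx / ax
        for j, (ay, my) in enumerate(y):
            if ay == 0.0:
                continue
            a = ax * ay
            m = a * (mean_x + my / ay)
            pa, pm = out[i + j]
            out[i + j] = (pa + a, pm + m)
    # drop a negligible tail to keep repeated convolution linear in practice
    while len(out) > 1 and out[-1][0] < cutoff:
        out.pop()
    return out


def _power(dist: _Dist, n: int) -> _Dist:
    result: _Dist = [(1.0, 0.0)]
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def isotope_pattern(
    f: ElementalFormula | str, max_isotopologues: int = 5
) -> IsotopePattern:
    """Simulate the nominal-mass isotope envelope of a formula.

    Per-element single-atom distributions are raised to their atom counts by
    repeated convolution and multiplied together; each nominal-mass bin
    carries the abundance-weighted mean exact mass. The result is truncated
    to ``max_isotopologues`` entries and normalized to base peak = 1.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if max_isotopologues < 1:
        raise ValueError("max_isotopologues must be >= 1")
    total: _Dist = [(1.0, 0.0)]
    for el, n in f.counts.items():
        total = _convolve(total, _power(_element_dist(el), n))
    pairs = [(m / a, a) for a, m in total if a > 0]
    pairs.sort()
    return IsotopePattern.from_pairs(pairs[:max_isotopologues])
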