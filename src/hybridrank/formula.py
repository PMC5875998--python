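"""Candidate elemental-formula enumeration and isotope-pattern ranking.

Given an accurate m/z and a declared adduct, recover the neutral
monoisotopic mass, enumerate every elemental formula within a ppm window
under per-element count bounds, and rank the candidates by how well their
simulated isotope envelope fits an observed one (falling back to |ppm| when
no envelope is available). This reproduces the formula-narrowing step that
turns an accurate-mass feature into a short list of chemical formulas.

Enumeration is a bounded depth-first count over elements ordered by
decreasing atomic mass with branch-and-bound mass pruning: complete within
the bounds, and fast at metabolite scale (< 1 kDa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .chem import (
    Adduct,
    ElementalFormula,
    IsotopePattern,
    get_adduct,
    isotope_pattern,
    monoisotopic_mass,
    neutral_mass_from_mz,
    ppm_error,
    rdbe,
)
from .elements import MONOISOTOPIC

__all__ = [
    "MassFeature",
    "ElementBounds",
    "FormulaCandidate",
    "enumerate_formulas",
    "isotope_fit_score",
    "infer_formula",
]

log = logging.getLogger(__name__)

#: hard cap on enumerated candidates before erroring out
DEFAULT_CANDIDATE_CAP = 200_000


@dataclass(frozen=True)
class MassFeature:
    """An accurate-mass LC-MS feature: observed m/z plus ion metadata."""

    mz: float
    polarity: str
    adduct: Adduct
    intensity: float | None = None
    isotope_envelope: IsotopePattern | None = None
    retention_time: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.isotope_envelope is not None:
            base = self.isotope_envelope.masses[0]
            if abs(base - self.mz) > 0.05:
                raise ValueError(
                    f"isotope envelope base peak {base:.4f} is not within "
                    f"0.05 Da of feature m/z {self.mz:.4f}"
                )

    @property
    def neutral_mass(self) -> float:
        return neutral_mass_from_mz(self.mz, self.adduct)


class ElementBounds:
    """Per-element (min, max) count bounds for formula enumeration."""

    def __init__(self, bounds: Mapping[str, tuple[int, int]]):
        if not bounds:
            raise ValueError("element bounds must not be empty")
        for el, (lo, hi) in bounds.items():
            if el not in MONOISOTOPIC:
                raise ValueError(f"unknown element in bounds: {el}")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")
        self.bounds = dict(bounds)

    @classmethod
    def chnops(cls, mass: float, extra: Mapping[str, tuple[int, int]] | None = None) -> "ElementBounds":
        """Default CHNOPS bounds with maxima scaled to the target mass."""
        b = {
            el: (0, int(mass / MONOISOTOPIC[el]) + 1)
            for el in ("C", "H", "N", "O", "P", "S")
        }
        if extra:
            b.update(extra)
        return cls(b)

    def items(self):
        return self.bounds.items()

    def __repr__(self) -> str:
        inner = ", ".join(f"{el}:{lo}-{hi}" for el, (lo, hi) in sorted(self.bounds.items()))
        return f"ElementBounds({inner})"


@dataclass(frozen=True)
class FormulaCandidate:
    """One enumerated formula with its fit diagnostics and 1-based rank."""

    formula: ElementalFormula
    ppm_error: float
    isotope_score: float | None
    rdbe: float
    rank: int


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float,
    bounds: ElementBounds,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
) -> list[ElementalFormula]:
    """All formulas within ``bounds`` whose mass is within ``tol_ppm``.

    Complete relative to the bounds; results sorted by |ppm error|.
    Raises if the bounds admit more than ``candidate_cap`` candidates.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo_mass = neutral_mass * (1 - tol_ppm * 1e-6)
    hi_mass = neutral_mass * (1 + tol_ppm * 1e-6)

    # heaviest first: tight pruning, light elements (H) fill in last
    order = sorted(bounds.items(), key=lambda kv: -MONOISOTOPIC[kv[0]])
    elements = [el for el, _ in order]
    masses = [MONOISOTOPIC[el] for el in elements]
    lows = [lo for _, (lo, hi) in order]
    highs = [hi for _, (lo, hi) in order]
    # minimal residual mass contributed by the remaining elements' minima
    min_tail = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        min_tail[i] = min_tail[i + 1] + lows[i] * masses[i]

    out: list[ElementalFormula] = []
    counts = [0] * len(elements)

    def recurse(i: int, acc_mass: float) -> None:
        if i == len(elements):
            if lo_mass <= acc_mass <= hi_mass and any(counts):
                if len(out) >= candidate_cap:
                    raise ValueError(
                        f"more than {candidate_cap} candidate formulas; "
                        "tighten the element bounds or ppm tolerance"
                    )
                out.append(
                    ElementalFormula(
                        {el: c for el, c in zip(elements, counts) if c}
                    )
                )
            return
        m = masses[i]
        lo_n, hi_n = lows[i], highs[i]
        # branch-and-bound: the remaining elements add at least min_tail[i+1]
        for n in range(lo_n, hi_n + 1):
            new_mass = acc_mass + n * m
            if new_mass + min_tail[i + 1] > hi_mass:
                break
            counts[i] = n
            recurse(i + 1, new_mass)
        counts[i] = 0

    recurse(0, 0.0)
    out.sort(key=lambda f: (abs(ppm_error(monoisotopic_mass(f), neutral_mass)), f.hill()))
    return out


def isotope_fit_score(
    observed: IsotopePattern, theoretical: IsotopePattern, k: int | None = None
) -> float:
    """Normalized-L1 agreement between two base-peak-normalized envelopes.

    score = 1 − Σ|obs − theo| / Σtheo over the first K aligned
    isotopologues (missing observed entries count as zero), clipped to
    [0, 1]. 1 iff the patterns agree exactly over K; parameter-free and
    bounded, so scores are comparable across candidates.
    """
    if not observed.isotopologues or not theoretical.isotopologues:
        raise ValueError("isotope patterns must be non-empty")
    if k is None:
        k = len(theoretical.isotopologues)
    obs = list(observed.abundances[:k]) + [0.0] * max(0, k - len(observed.abundances))
    theo = list(theoretical.abundances[:k]) + [0.0] * max(0, k - len(theoretical.abundances))
    denom = sum(theo)
    if denom <= 0:
        raise ValueError("theoretical pattern has zero total abundance")
    score = 1.0 - sum(abs(o - t) for o, t in zip(obs, theo)) / denom
    return min(1.0, max(0.0, score))


def _rdbe_plausible(f: ElementalFormula) -> bool:
    r = rdbe(f)
    if r < 0:
        return False
    # half-integer RDBE marks an odd-electron (radical) composition
    return abs(2 * r - round(2 * r)) < 1e-9 and abs(r - round(r)) < 1e-9


def infer_formula(
    feature: MassFeature,
    tol_ppm: float = 10.0,
    bounds: ElementBounds | None = None,
    max_isotopologues: int = 3,
    rdbe_filter: bool = True,
) -> list[FormulaCandidate]:
    """Rank candidate formulas for a mass feature.

    The neutral mass is recovered through the feature's declared adduct.
    Candidates failing the RDBE plausibility filter (negative or
    half-integer RDBE) are dropped unless ``rdbe_filter`` is off. With an
    isotope envelope the ranking is (isotope score desc, |ppm| asc);
    without one it is |ppm| alone. Returns an empty list (with a logged
    warning) when nothing falls inside the tolerance.
    """
    neutral = feature.neutral_mass
    if bounds is None:
        bounds = ElementBounds.chnops(neutral)
    formulas = enumerate_formulas(neutral, tol_ppm, bounds)
    if rdbe_filter:
        formulas = [f for f in formulas if _rdbe_plausible(f)]
    if not formulas:
        log.warning(
            "no candidate formula within %.1f ppm of neutral mass %.5f "
            "(feature m/z %.5f, adduct %s)",
            tol_ppm, neutral, feature.mz, feature.adduct.name,
        )
        return []

    scored = []
    for f in formulas:
        perr = ppm_error(monoisotopic_mass(f), neutral)
        iso = None
        if feature.isotope_envelope is not None:
            iso = isotope_fit_score(
                feature.isotope_envelope, isotope_pattern(f, max_isotopologues)
            )
        scored.append((f, perr, iso))

    if feature.isotope_envelope is not None:
        scored.sort(key=lambda t: (-t[2], abs(t[1]), t[0].hill()))
    else:
        scored.sort(key=lambda t: (abs(t[1]), t[0].hill()))

    return [
        FormulaCandidate(formula=f, ppm_error=perr, isotope_score=iso,
                         rdbe=rdbe(f), rank=i + 1)
        for i, (f, perr, iso) in enumerate(scored)
    ]
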