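"""Weighted HSQC peak-list matching and NMR candidate ranking.

The central NMR operation of the toolkit: compare a candidate structure's
*predicted* 2D ¹³C-¹H HSQC cross-peaks against an *experimental* peak list.
Each predicted/experimental peak pair gets a weighted Euclidean distance in
(δ¹H, δ¹³C) space — ¹H shifts are weighted 10× relative to ¹³C, reflecting
the ~10-fold narrower proton shift dispersion — and peaks are paired one-to-
one, closest pairs first, subject to per-dimension cutoffs. A candidate is
summarized by its matching ratio (matched / predicted cross-peaks) and its
mean per-dimension shift error over matched pairs; candidates are ranked by
maximum matching ratio, then minimum weighted mean distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "HsqcPeak",
    "HsqcPeakList",
    "ShiftWeights",
    "MatchConfig",
    "HsqcMatchResult",
    "weighted_peak_distance",
    "match_peak_lists",
    "rank_nmr_candidates",
]

# typical solution-state shift ranges; violations warn but are not rejected
_H_RANGE = (-2.0, 15.0)
_C_RANGE = (-10.0, 230.0)


@dataclass(frozen=True)
class HsqcPeak:
    """One HSQC cross-peak: attached-proton and carbon chemical shifts (ppm)."""

    h_shift: float
    c_shift: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_shift) and math.isfinite(self.c_shift)):
            raise ValueError("chemical shifts must be finite")
        if not (_H_RANGE[0] <= self.h_shift <= _H_RANGE[1]) or not (
            _C_RANGE[0] <= self.c_shift <= _C_RANGE[1]
        ):
            warnings.warn(
                f"HSQC peak ({self.h_shift}, {self.c_shift}) outside typical "
                f"¹H {_H_RANGE} / ¹³C {_C_RANGE} ppm ranges",
                stacklevel=2,
            )


@dataclass(frozen=True)
class HsqcPeakList:
    """A labeled experimental or predicted HSQC peak list."""

    label: str
    kind: Literal["experimental", "predicted"]
    peaks: tuple[HsqcPeak, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("experimental", "predicted"):
            raise ValueError(f"kind must be experimental/predicted, got {self.kind!r}")
        if not self.peaks:
            raise ValueError(f"peak list {self.label!r} must have at least one peak")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class ShiftWeights:
    """Dimensionless per-dimension weights for the shift distance."""

    w_h: float = 10.0
    w_c: float = 1.0

    def __post_init__(self) -> None:
        if self.w_h <= 0 or self.w_c <= 0:
            raise ValueError("shift weights must be positive")


@dataclass(frozen=True)
class MatchConfig:
    """Matching tolerances, weights and assignment strategy.

    ``max_dh``/``max_dc`` are per-dimension cutoffs (ppm) beyond which a
    predicted/experimental pair can never match. ``assignment`` selects the
    pairing algorithm: greedy nearest-first (default) or globally optimal
    minimum-total-distance bipartite assignment.
    """

    weights: ShiftWeights = field(default_factory=ShiftWeights)
    max_dh: float = 0.5
    max_dc: float = 5.0
    ratio_decimals: int = 2
    assignment: Literal["greedy", "optimal"] = "greedy"

    def __post_init__(self) -> None:
        if self.max_dh <= 0 or self.max_dc <= 0:
            raise ValueError("match cutoffs must be positive")


@dataclass(frozen=True)
class HsqcMatchResult:
    """Outcome of matching one predicted list against one experimental list.

    ``pairs`` holds (predicted index, experimental index) tuples;
    ``matching_ratio`` = |pairs| / predicted peak count; the mean shift
    errors are over matched pairs only and are NaN when nothing matched.
    ``rank_key`` sorts better candidates first: higher ratio, then smaller
    weighted mean distance.
    """

    candidate_label: str
    experimental_label: str
    pairs: tuple[tuple[int, int], ...]
    mean_dh: float
    mean_dc: float
    matching_ratio: float
    weighted_mean_distance: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def ratio_rounded(self) -> float:
        return round(self.matching_ratio, 2)

    @property
    def rank_key(self) -> tuple[float, float]:
        wd = self.weighted_mean_distance
        return (-self.matching_ratio, wd if math.isfinite(wd) else math.inf)


def weighted_peak_distance(p: HsqcPeak, q: HsqcPeak, w: ShiftWeights) -> float:
    """Weighted Euclidean distance √((w_h·Δδ¹H)² + (w_c·Δδ¹³C)²)."""
    return math.hypot(w.w_h * (p.h_shift - q.h_shift), w.w_c * (p.c_shift - q.c_shift))


def _distance_matrix(
    predicted: Sequence[HsqcPeak], experimental: Sequence[HsqcPeak], w: ShiftWeights
) -> np.ndarray:
    ph = np.array([p.h_shift for p in predicted])
    pc = np.array([p.c_shift for p in predicted])
    eh = np.array([q.h_shift for q in experimental])
    ec = np.array([q.c_shift for q in experimental])
    return np.hypot(
        w.w_h * (ph[:, None] - eh[None, :]), w.w_c * (pc[:, None] - ec[None, :])
    )


def _admissible(
    predicted: Sequence[HsqcPeak], experimental: Sequence[HsqcPeak], cfg: MatchConfig
) -> np.ndarray:
    ph = np.array([p.h_shift for p in predicted])
    pc = np.array([p.c_shift for p in predicted])
    eh = np.array([q.h_shift for q in experimental])
    ec = np.array([q.c_shift for q in experimental])
    return (np.abs(ph[:, None] - eh[None, :]) <= cfg.max_dh) & (
        np.abs(pc[:, None] - ec[None, :]) <= cfg.max_dc
    )


def _assign_greedy(
    dist: np.ndarray, ok: np.ndarray
) -> list[tuple[int, int]]:
    order = sorted(
        ((dist[i, j], i, j) for i, j in zip(*np.nonzero(ok))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_p: set[int] = set()
    used_e: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for d, i, j in order:
        if i in used_p or j in used_e:
            continue
        pairs.append((i, j))
        used_p.add(i)
        used_e.add(j)
    return pairs


def _assign_optimal(dist: np.ndarray, ok: np.ndarray) -> list[tuple[int, int]]:
    # forbid out-of-cutoff pairs with a penalty larger than any feasible total
    penalty = dist[ok].sum() + dist.max() + 1.0 if ok.any() else 1.0
    cost = np.where(ok, dist, penalty)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if ok[i, j]]


def match_peak_lists(
    predicted: HsqcPeakList, experimental: HsqcPeakList, cfg: MatchConfig | None = None
) -> HsqcMatchResult:
    """Match a predicted HSQC peak list to an experimental one.

    Builds the full weighted distance matrix, pairs peaks one-to-one
    (greedy nearest-first by default; optimal bipartite by config) while
    skipping pairs outside the per-dimension cutoffs, and summarizes the
    outcome. The matching-ratio denominator is the predicted peak count, so
    a 6-cross-peak prediction with 5 matches scores 5/6 ≈ 0.83.
    """
    cfg = cfg or MatchConfig()
    if predicted.kind != "predicted":
        raise ValueError(f"first argument must be a predicted list, got {predicted.kind}")
    if experimental.kind != "experimental":
        raise ValueError(
            f"second argument must be an experimental list, got {experimental.kind}"
        )
    dist = _distance_matrix(predicted.peaks, experimental.peaks, cfg.weights)
    ok = _admissible(predicted.peaks, experimental.peaks, cfg)
    if cfg.assignment == "greedy":
        pairs = _assign_greedy(dist, ok)
    else:
        pairs = _assign_optimal(dist, ok)
    pairs.sort()

    if pairs:
        dh = float(np.mean([abs(predicted.peaks[i].h_shift - experimental.peaks[j].h_shift)
                            for i, j in pairs]))
        dc = float(np.mean([abs(predicted.peaks[i].c_shift - experimental.peaks[j].c_shift)
                            for i, j in pairs]))
        wd = float(np.mean([dist[i, j] for i, j in pairs]))
    else:
        dh = dc = wd = math.nan
    return HsqcMatchResult(
        candidate_label=predicted.label,
        experimental_label=experimental.label,
        pairs=tuple(pairs),
        mean_dh=dh,
        mean_dc=dc,
        matching_ratio=len(pairs) / len(predicted.peaks),
        weighted_mean_distance=wd,
    )


def rank_nmr_candidates(
    candidates: Sequence[HsqcPeakList],
    experimental: HsqcPeakList,
    cfg: MatchConfig | None = None,
) -> list[tuple[int, HsqcMatchResult]]:
    """Rank candidate predicted peak lists against one experimental list.

    Returns (rank, result) pairs sorted by matching ratio descending, then
    weighted mean distance ascending, then candidate label; ranks are dense
    and 1-based (exact ties on the sort key share a rank).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    labels = [c.label for c in candidates]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate candidate labels: {dupes}")
    results = [match_peak_lists(c, experimental, cfg) for c in candidates]
    results.sort(key=lambda r: (*r.rank_key, r.candidate_label))
    ranked: list[tuple[int, HsqcMatchResult]] = []
    rank = 0
    prev_key = None
    for r in results:
        if r.rank_key != prev_key:
            rank += 1
            prev_key = r.rank_key
        ranked.append((rank, r))
    return ranked
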