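"""Mixture workflow: spin-system deconvolution, pairwise ranking, consensus.

In an unfractionated sample the experimental HSQC contains cross-peaks from
several metabolites at once, and multiple LC-MS features (each with its own
candidate-structure set) must be matched against it without knowing which
peaks belong to which feature. The workflow here:

1. *Deconvolute* the HSQC into per-metabolite peak groups using ¹H-¹H TOCSY
   (and optionally HMBC) connectivity: peaks whose proton shifts co-occur in
   a TOCSY cross-peak belong to the same spin system, so connected
   components of that graph partition the HSQC peak list.
2. Run *all pairwise* comparisons — every candidate of every feature against
   every peak group — and order them globally.
3. *Combine* the NMR ranking with the orthogonal MS² ranking by rank
   product, so a candidate must do well on both axes to stay on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .fragment import Ms2Score
from .hsqc import HsqcMatchResult, HsqcPeakList, MatchConfig, match_peak_lists

__all__ = [
    "TocsyPeak",
    "PeakGroup",
    "PairwiseRanking",
    "EvidenceRanking",
    "group_peaks_by_connectivity",
    "pairwise_nmr_rank",
    "combine_evidence",
]


@dataclass(frozen=True)
class TocsyPeak:
    """A ¹H-¹H TOCSY cross-peak, canonicalized so h1 ≤ h2."""

    h1: float
    h2: float

    def __post_init__(self) -> None:
        a, b = sorted((float(self.h1), float(self.h2)))
        object.__setattr__(self, "h1", a)
        object.__setattr__(self, "h2", b)


@dataclass(frozen=True)
class PeakGroup:
    """A deconvoluted subset of the experimental HSQC peak list."""

    group_id: str
    peaks: HsqcPeakList


def group_peaks_by_connectivity(
    hsqc: HsqcPeakList,
    tocsy: Sequence[TocsyPeak],
    tol_h: float = 0.02,
    extra_edges: Sequence[TocsyPeak] = (),
) -> list[PeakGroup]:
    """Partition HSQC peaks into spin systems via TOCSY connectivity.

    Two HSQC peaks are connected when some TOCSY cross-peak's (h1, h2)
    matches their ¹H shifts within ``tol_h`` ppm (either orientation).
    Groups are the connected components; with no TOCSY peaks every HSQC
    peak is its own group. ``extra_edges`` accepts additional connectivity
    (e.g. HMBC-derived) in the same form. Group ids are assigned
    deterministically in order of each group's lowest ¹H shift.
    """
    if hsqc.kind != "experimental":
        raise ValueError("deconvolution applies to an experimental peak list")
    if tol_h <= 0:
        raise ValueError("tol_h must be positive")
    g = nx.Graph()
    g.add_nodes_from(range(len(hsqc.peaks)))
    edges = list(tocsy) + list(extra_edges)
    for t in edges:
        for i, p in enumerate(hsqc.peaks):
            for j, q in enumerate(hsqc.peaks):
                if i >= j:
                    continue
                match_fwd = abs(p.h_shift - t.h1) <= tol_h and abs(q.h_shift - t.h2) <= tol_h
                match_rev = abs(p.h_shift - t.h2) <= tol_h and abs(q.h_shift - t.h1) <= tol_h
                if match_fwd or match_rev:
                    g.add_edge(i, j)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: min(hsqc.peaks[i].h_shift for i in c),
    )
    groups = [
        PeakGroup(
            group_id=f"G{k + 1}",
            peaks=HsqcPeakList(
                label=f"{hsqc.label}/G{k + 1}",
                kind="experimental",
                peaks=tuple(hsqc.peaks[i] for i in comp),
            ),
        )
        for k, comp in enumerate(comps)
    ]
    # partition property: disjoint and covering, by construction — assert it
    covered = [i for comp in comps for i in comp]
    assert sorted(covered) == list(range(len(hsqc.peaks)))
    return groups


@dataclass(frozen=True)
class PairwiseRanking:
    """Globally ordered candidate × peak-group comparisons.

    ``rows`` holds one (candidate label, group id, match result) triple per
    pair, best first; ``best_per_group`` maps each group id to its best row.
    """

    rows: tuple[tuple[str, str, HsqcMatchResult], ...]
    best_per_group: Mapping[str, tuple[str, str, HsqcMatchResult]]

    @property
    def best(self) -> tuple[str, str, HsqcMatchResult]:
        return self.rows[0]


def pairwise_nmr_rank(
    candidate_sets: Mapping[str, Sequence[HsqcPeakList]],
    groups: Sequence[PeakGroup],
    cfg: MatchConfig | None = None,
) -> PairwiseRanking:
    """Score every candidate of every feature against every peak group.

    ``candidate_sets`` maps a feature id to its predicted peak lists;
    candidate labels must be unique across features. Rows are ordered by
    (matching ratio desc, weighted mean distance asc, candidate label,
    group id); with one candidate set and one group this reduces to plain
    single-spectrum candidate ranking.
    """
    if not candidate_sets or not groups:
        raise ValueError("need at least one candidate set and one peak group")
    labels = [c.label for cands in candidate_sets.values() for c in cands]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate candidate labels across sets: {dupes}")

    rows: list[tuple[str, str, HsqcMatchResult]] = []
    for _feature, cands in candidate_sets.items():
        for cand in cands:
            for grp in groups:
                res = match_peak_lists(cand, grp.peaks, cfg)
                rows.append((cand.label, grp.group_id, res))
    rows.sort(key=lambda r: (*r[2].rank_key, r[0], r[1]))
    best_per_group: dict[str, tuple[str, str, HsqcMatchResult]] = {}
    for row in rows:
        best_per_group.setdefault(row[1], row)
    return PairwiseRanking(rows=tuple(rows), best_per_group=best_per_group)


@dataclass(frozen=True)
class EvidenceRanking:
    """Consensus over NMR and MS² ranks.

    ``rows``: (candidate label, nmr_rank, ms2_rank, combined_key,
    combined_rank), ordered best first. Combined key is the rank product;
    combined ranks are dense and 1-based.
    """

    rows: tuple[tuple[str, int, int, float, int], ...]

    def rank_of(self, label: str) -> int:
        for row in self.rows:
            if row[0] == label:
                return row[4]
        raise KeyError(label)


def combine_evidence(
    nmr: Sequence[tuple[int, HsqcMatchResult]] | Mapping[str, int],
    ms2: Sequence[Ms2Score] | Mapping[str, int],
    method: str = "rank_product",
) -> EvidenceRanking:
    """Combine NMR and MS² candidate rankings into a consensus order.

    Accepts either ranked result objects or plain label→rank maps. A
    candidate absent from one ranking is imputed the worst rank of that
    ranking plus one, so nothing is silently dropped. Default combination
    is the rank product, sorted ascending with ties broken by NMR rank
    then label. The label sets must overlap.
    """
    if method != "rank_product":
        raise ValueError(f"unknown combination method: {method!r}")

    def as_map(obj) -> dict[str, int]:
        if isinstance(obj, Mapping):
            return dict(obj)
        out: dict[str, int] = {}
        for item in obj:
            if isinstance(item, Ms2Score):
                out[item.candidate_label] = item.rank
            else:
                rank, res = item
                out[res.candidate_label] = rank
        return out

    nmr_ranks = as_map(nmr)
    ms2_ranks = as_map(ms2)
    if not nmr_ranks or not ms2_ranks:
        raise ValueError("both rankings must be non-empty")
    if not set(nmr_ranks) & set(ms2_ranks):
        raise ValueError("NMR and MS2 rankings share no candidate labels")

    worst_nmr = max(nmr_ranks.values()) + 1
    worst_ms2 = max(ms2_ranks.values()) + 1
    labels = sorted(set(nmr_ranks) | set(ms2_ranks))
    scored = []
    for label in labels:
        rn = nmr_ranks.get(label, worst_nmr)
        rm = ms2_ranks.get(label, worst_ms2)
        scored.append((label, rn, rm, float(rn * rm)))
    scored.sort(key=lambda t: (t[3], t[1], t[0]))

    rows = []
    rank = 0
    prev = None
    for label, rn, rm, key in scored:
        if key != prev:
            rank += 1
            prev = key
        rows.append((label, rn, rm, key, rank))
    return EvidenceRanking(rows=tuple(rows))
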