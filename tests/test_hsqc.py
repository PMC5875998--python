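"""HSQC peak-list matching: distances, matching ratio, candidate ranking."""

import itertools
import math

import numpy as np
import pytest

from hybridrank.hsqc import (
    HsqcPeak,
    HsqcPeakList,
    MatchConfig,
    ShiftWeights,
    match_peak_lists,
    rank_nmr_candidates,
    weighted_peak_distance,
)
from tests.conftest import random_peak_list


def _as_list(label, kind, pairs):
    return HsqcPeakList(label=label, kind=kind, peaks=tuple(HsqcPeak(h, c) for h, c in pairs))


def test_weighted_distance_examples():
    w = ShiftWeights(10, 1)
    p = HsqcPeak(2.55, 39.57)
    q = HsqcPeak(2.70, 39.06)
    assert weighted_peak_distance(p, p, w) == 0.0
    assert weighted_peak_distance(p, q, w) == pytest.approx(1.5843, abs=1e-4)
    assert weighted_peak_distance(HsqcPeak(1.0, 20.0), HsqcPeak(1.1, 20.0), w) == pytest.approx(1.0)


def test_distance_is_symmetric():
    w = ShiftWeights()
    p, q = HsqcPeak(3.1, 55.0), HsqcPeak(2.9, 61.0)
    assert weighted_peak_distance(p, q, w) == weighted_peak_distance(q, p, w)


def test_self_match_is_perfect(square_peaks):
    pred = HsqcPeakList(label="self", kind="predicted", peaks=square_peaks.peaks)
    res = match_peak_lists(pred, square_peaks)
    assert res.matching_ratio == 1.0
    assert res.mean_dh == 0.0 and res.mean_dc == 0.0
    assert len(res.pairs) == 4


def test_matching_ratio_five_of_six_prints_083():
    """A 6-cross-peak prediction with one peak far off matches 5/6 → 0.83."""
    exp = _as_list("exp", "experimental", [(1.0, 20), (2.0, 30), (3.0, 40), (4.0, 50), (5.0, 60)])
    pred = _as_list(
        "cand", "predicted",
        [(1.02, 20.5), (2.01, 29.8), (3.05, 40.2), (3.98, 50.1), (4.97, 59.5), (8.5, 130.0)],
    )
    res = match_peak_lists(pred, exp)
    assert res.n_matched == 5
    assert f"{res.matching_ratio:.2f}" == "0.83"


def test_no_match_flags_means_and_ranks_last(square_peaks):
    far = _as_list("far", "predicted", [(8.5, 170.0), (9.0, 180.0)])
    near = HsqcPeakList(label="near", kind="predicted", peaks=square_peaks.peaks)
    res = match_peak_lists(far, square_peaks)
    assert res.matching_ratio == 0.0
    assert math.isnan(res.mean_dh) and math.isnan(res.mean_dc)
    ranked = rank_nmr_candidates([far, near], square_peaks)
    assert ranked[0][1].candidate_label == "near"
    assert ranked[-1][1].candidate_label == "far"


def test_kind_mismatch_rejected(square_peaks):
    with pytest.raises(ValueError):
        match_peak_lists(square_peaks, square_peaks)


def test_one_to_one_matching_prevents_collapse():
    """Many predicted peaks near one experimental peak yield one match only."""
    exp = _as_list("exp", "experimental", [(3.0, 40.0)])
    pred = _as_list("cand", "predicted", [(3.0, 40.0), (3.01, 40.1), (3.02, 40.2)])
    res = match_peak_lists(pred, exp)
    assert res.n_matched == 1
    assert res.matching_ratio == pytest.approx(1 / 3)


def test_rank_single_candidate_is_one(square_peaks):
    pred = HsqcPeakList(label="only", kind="predicted", peaks=square_peaks.peaks)
    assert rank_nmr_candidates([pred], square_peaks)[0][0] == 1


def test_true_candidate_beats_decoys(rng, square_peaks):
    """A σ=(0.02, 0.2) perturbed truth outranks 20 far-away decoys."""
    peaks = tuple(
        HsqcPeak(p.h_shift + rng.normal(0, 0.02), p.c_shift + rng.normal(0, 0.2))
        for p in square_peaks.peaks
    )
    true_cand = HsqcPeakList(label="truth", kind="predicted", peaks=peaks)
    decoys = []
    for d in range(20):
        dpeaks = []
        while len(dpeaks) < 4:
            h, c = rng.uniform(0.5, 9.5), rng.uniform(10, 145)
            if all(abs(h - p.h_shift) >= 1.0 for p in square_peaks.peaks):
                dpeaks.append(HsqcPeak(h, c))
        decoys.append(HsqcPeakList(label=f"decoy{d}", kind="predicted", peaks=tuple(dpeaks)))
    ranked = rank_nmr_candidates([true_cand, *decoys], square_peaks)
    assert ranked[0][1].candidate_label == "truth"


def test_tie_broken_by_label(square_peaks):
    a = HsqcPeakList(label="aaa", kind="predicted", peaks=square_peaks.peaks)
    b = HsqcPeakList(label="bbb", kind="predicted", peaks=square_peaks.peaks)
    ranked = rank_nmr_candidates([b, a], square_peaks)
    assert [r.candidate_label for _, r in ranked] == ["aaa", "bbb"]
    assert [rank for rank, _ in ranked] == [1, 1]  # identical key → shared dense rank


def test_duplicate_labels_rejected(square_peaks):
    a = HsqcPeakList(label="x", kind="predicted", peaks=square_peaks.peaks)
    with pytest.raises(ValueError, match="duplicate"):
        rank_nmr_candidates([a, a], square_peaks)


def _brute_force_assignment(pred, exp, cfg):
    """Max-cardinality, min-total-distance assignment by permutation search."""
    w = cfg.weights
    n, m = len(pred.peaks), len(exp.peaks)
    for size in range(min(n, m), -1, -1):
        best_cost = math.inf
        for pred_sub in itertools.combinations(range(n), size):
            for chosen in itertools.permutations(range(m), size):
                cost, ok = 0.0, True
                for i, j in zip(pred_sub, chosen):
                    p, q = pred.peaks[i], exp.peaks[j]
                    if (abs(p.h_shift - q.h_shift) > cfg.max_dh
                            or abs(p.c_shift - q.c_shift) > cfg.max_dc):
                        ok = False
                        break
                    cost += weighted_peak_distance(p, q, w)
                if ok and cost < best_cost:
                    best_cost = cost
        if math.isfinite(best_cost):
            return size, best_cost
    return 0, 0.0


def test_greedy_matches_optimal_on_small_instances(rng):
    """Greedy assignment equals the optimal bipartite one on random ≤5-peak lists."""
    cfg = MatchConfig()
    agree = 0
    total = 40
    for t in range(total):
        exp = random_peak_list(rng, int(rng.integers(2, 6)), "exp", "experimental")
        pred = random_peak_list(rng, int(rng.integers(2, 6)), "pred", "predicted")
        greedy = match_peak_lists(pred, exp, cfg)
        opt_cfg = MatchConfig(assignment="optimal")
        opt = match_peak_lists(pred, exp, opt_cfg)
        n_best, _cost = _brute_force_assignment(pred, exp, cfg)
        assert opt.n_matched == n_best
        agree += greedy.n_matched == n_best
    assert agree == total


def test_rank_invariant_under_weight_scaling(rng, square_peaks):
    cands = [random_peak_list(rng, 4, f"c{i}") for i in range(8)]
    base = rank_nmr_candidates(cands, square_peaks, MatchConfig(weights=ShiftWeights(10, 1)))
    scaled = rank_nmr_candidates(cands, square_peaks, MatchConfig(weights=ShiftWeights(20, 2)))
    assert [r.candidate_label for _, r in base] == [r.candidate_label for _, r in scaled]


def test_adding_decoy_never_changes_existing_scores(rng, square_peaks):
    cands = [random_peak_list(rng, 4, f"c{i}") for i in range(5)]
    before = {r.candidate_label: (r.matching_ratio, r.weighted_mean_distance)
              for _, r in rank_nmr_candidates(cands, square_peaks)}
    extra = random_peak_list(rng, 4, "extra")
    after = {r.candidate_label: (r.matching_ratio, r.weighted_mean_distance)
             for _, r in rank_nmr_candidates(cands + [extra], square_peaks)}
    for label, score in before.items():
        got = after[label]
        assert got[0] == score[0]
        assert got[1] == score[1] or (math.isnan(got[1]) and math.isnan(score[1]))
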