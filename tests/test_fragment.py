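"""In-silico fragmentation, spectrum annotation and MS2 candidate scoring."""

import networkx as nx
import pytest
from rdkit import Chem

from hybridrank.chem import get_adduct, monoisotopic_mass
from hybridrank.elements import PROTON_MASS
from hybridrank.fragment import (
    Fragment,
    Ms2Spectrum,
    annotate_spectrum,
    generate_fragments,
    rank_ms2_candidates,
    score_ms2_candidate,
)

GLUCORAPHANIN = "C(C1C(C(C(C(O1)SC(=NOS(=O)(=O)O)CCCCS(=O)C)O)O)O)O"


def test_ethane_single_cleavage_yields_methyl():
    frags = generate_fragments("CC", max_bond_breaks=1, max_tree_depth=1)
    formulas = {f.formula.hill() for f in frags}
    assert "CH3" in formulas
    assert "C2H6" in formulas  # intact molecule always present


def test_benzene_one_cut_gives_no_proper_fragment():
    frags = generate_fragments("c1ccccc1", max_bond_breaks=1, max_tree_depth=1)
    assert {f.formula.hill() for f in frags} == {"C6H6"}


def test_benzene_two_cuts_open_the_ring():
    frags = generate_fragments("c1ccccc1", max_bond_breaks=2, max_tree_depth=1)
    assert any(f.formula["C"] < 6 for f in frags)


def test_zero_breaks_returns_only_intact_molecule():
    frags = generate_fragments("CC(C)C(N)C(=O)O", max_bond_breaks=0, max_tree_depth=2)
    assert len(frags) == 1
    assert frags[0].formula.hill() == "C5H11NO2"
    assert frags[0].bonds_broken == 0 and frags[0].h_shift == 0


def test_unparsable_structure_reported():
    with pytest.raises(ValueError, match="not-a-smiles"):
        generate_fragments("not-a-smiles", 1, 1)


@pytest.mark.parametrize("smiles", ["CC(C)C(N)C(=O)O", "CSCCC(N)C(=O)O", "OC(=O)c1cccnc1"])
def test_fragment_closure(smiles):
    """Fragment formulas are sub-formulas of the parent, masses smaller."""
    parent = generate_fragments(smiles, 0, 0)[0]
    for f in generate_fragments(smiles, 2, 2):
        assert parent.formula.contains(f.formula)
        if f.atom_subset != parent.atom_subset:
            assert f.neutral_mass < parent.neutral_mass
            assert f.bonds_broken >= 1


def _component_formula(mol, atoms):
    counts = {}
    n_h = 0
    for idx in atoms:
        a = mol.GetAtomWithIdx(idx)
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        n_h += a.GetTotalNumHs()
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    from hybridrank.chem import ElementalFormula

    return ElementalFormula(counts).hill()


def _bridge_oracle(mol):
    """Independent 1-break oracle: formulas of the components obtained by
    deleting each bridge edge (ring bonds never disconnect with one cut)."""
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    formulas = set()
    for edge in nx.bridges(g):
        h = g.copy()
        h.remove_edge(*edge)
        for comp in nx.connected_components(h):
            formulas.add(_component_formula(mol, comp))
    return formulas


@pytest.mark.parametrize(
    "smiles",
    ["CC(C)C(N)C(=O)O", "CCOC(=O)C", "c1ccccc1C", "CC1CC1O", "NC(=O)CCC(N)C(=O)O"],
)
def test_one_break_fragments_equal_bridge_enumeration(smiles):
    mol = Chem.MolFromSmiles(smiles)
    frags = generate_fragments(smiles, max_bond_breaks=1, max_tree_depth=1)
    got = {f.formula.hill() for f in frags if f.bonds_broken == 1 and f.h_shift == 0}
    assert got == _bridge_oracle(mol)


def _spectrum(peaks, polarity="negative", precursor=500.0):
    return Ms2Spectrum(precursor_mz=precursor, polarity=polarity, peaks=tuple(peaks))


def test_annotate_exact_peak_matches_at_zero_ppm():
    frags = generate_fragments("CC", 1, 1)
    adduct = get_adduct("[M+H]+")
    target = next(f for f in frags if f.formula.hill() == "CH3" and f.h_shift == 0)
    sp = _spectrum([(target.ion_mz(adduct), 100.0)], polarity="positive", precursor=31.0)
    ann = annotate_spectrum(frags, sp, tol_ppm=30, adduct=adduct)
    assert 0 in ann.matches
    frag, err = ann.matches[0]
    assert err == 0.0


def test_annotate_peak_beyond_tolerance_unmatched():
    frags = generate_fragments("CC", 1, 1)
    adduct = get_adduct("[M+H]+")
    mz = frags[0].ion_mz(adduct) * (1 + 50e-6)
    sp = _spectrum([(mz, 10.0)], polarity="positive", precursor=31.0)
    ann = annotate_spectrum(frags, sp, tol_ppm=30, adduct=adduct)
    assert ann.unmatched == (0,)


def test_glucoraphanin_sulfate_fragment_matched_within_30ppm():
    """The deprotonated C5H9NO4S fragment explains the 178.0166 peak."""
    frags = generate_fragments(GLUCORAPHANIN, 2, 2)
    sp = _spectrum([(178.0166, 100.0)], polarity="negative", precursor=436.0332)
    ann = annotate_spectrum(frags, sp, tol_ppm=30, adduct="[M-H]-")
    assert 0 in ann.matches
    frag, err = ann.matches[0]
    theoretical = monoisotopic_mass("C5H9NO4S") - PROTON_MASS
    assert theoretical == pytest.approx(178.017952, abs=1e-4)
    assert abs(err) == pytest.approx(7.6, abs=0.5)


def test_tolerance_widening_never_unmatches():
    frags = generate_fragments("CC(C)C(N)C(=O)O", 2, 2)
    sp = _spectrum(
        [(72.0808, 50.0), (118.0863, 100.0), (90.0, 5.0)],
        polarity="positive",
        precursor=118.0863,
    )
    narrow = annotate_spectrum(frags, sp, tol_ppm=10, adduct="[M+H]+")
    wide = annotate_spectrum(frags, sp, tol_ppm=50, adduct="[M+H]+")
    assert set(narrow.matches) <= set(wide.matches)


def test_score_examples():
    sp = _spectrum([(100.0, 50.0), (200.0, 25.0)], polarity="positive", precursor=300.0)
    frag = Fragment(frozenset({0}), None, 0.0, 0, 0)
    from hybridrank.fragment import Ms2Annotation

    none = Ms2Annotation(matches={}, unmatched=(0, 1), n_peaks=2)
    assert score_ms2_candidate(none, sp) == 0.0
    base_only = Ms2Annotation(matches={0: (frag, 0.0)}, unmatched=(1,), n_peaks=2)
    both = Ms2Annotation(matches={0: (frag, 0.0), 1: (frag, 0.0)}, unmatched=(), n_peaks=2)
    s1, s2 = score_ms2_candidate(base_only, sp), score_ms2_candidate(both, sp)
    assert s1 == pytest.approx(1.0**0.6 * 100.0**3)
    assert s2 > s1  # adding a matched peak never decreases the score


def test_score_is_intensity_scale_invariant():
    from hybridrank.fragment import Ms2Annotation

    frag = Fragment(frozenset({0}), None, 0.0, 0, 0)
    ann = Ms2Annotation(matches={0: (frag, 0.0), 1: (frag, 0.0)}, unmatched=(), n_peaks=2)
    sp1 = _spectrum([(100.0, 10.0), (150.0, 5.0)], "positive", 300.0)
    sp2 = _spectrum([(100.0, 1000.0), (150.0, 500.0)], "positive", 300.0)
    assert score_ms2_candidate(ann, sp1) == pytest.approx(score_ms2_candidate(ann, sp2))


def test_rank_recovers_true_structure_against_mass_disjoint_decoys():
    from hybridrank.simulate import simulate_ms2

    true_smiles = "CSCCC(N)C(=O)O"  # methionine
    decoys = {
        "phenylalanine": "NC(Cc1ccccc1)C(=O)O",
        "thymidine": "Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O",
        "nicotinate": "OC(=O)c1cccnc1",
    }
    sp = simulate_ms2(true_smiles, n_noise_peaks=0, seed=7, subset_fraction=1.0)
    scores = rank_ms2_candidates({"methionine": true_smiles, **decoys}, sp)
    assert scores[0].candidate_label == "methionine"
    assert scores[0].normalized_score == 1.0
    assert scores[0].rank == 1


def test_all_zero_scores_warned_and_ranked_by_label(caplog):
    sp = _spectrum([(999.9, 10.0)], polarity="positive", precursor=1000.0)
    with caplog.at_level("WARNING"):
        scores = rank_ms2_candidates({"b": "CC", "a": "CCO"}, sp)
    assert [s.candidate_label for s in scores] == ["a", "b"]
    assert all(s.normalized_score == 0.0 for s in scores)
    assert any("zero" in r.message for r in caplog.records)


def test_single_candidate_with_match_scores_one():
    frags = generate_fragments("CC", 1, 1)
    adduct = get_adduct("[M+H]+")
    target = next(f for f in frags if f.formula.hill() == "CH3" and f.h_shift == 0)
    sp = _spectrum([(target.ion_mz(adduct), 10.0)], polarity="positive", precursor=31.0)
    scores = rank_ms2_candidates({"ethane": "CC"}, sp)
    assert scores[0].normalized_score == 1.0
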