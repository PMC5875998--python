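"""In-silico MS/MS fragmentation and candidate scoring.

Candidate structures are fragmented by systematic bond disconnection: the
heavy-atom graph of the molecule is cut at up to ``max_bond_breaks`` bonds
per step, recursively to ``max_tree_depth`` levels, and every connected
piece becomes a fragment. Breaking a bridge (acyclic) bond splits the graph
with one cut; a ring requires two cuts, which is why a single cut of
benzene yields no proper fragment. Each fragment is emitted with hydrogen-
rearrangement variants (±2 H) to account for H transfers during collision-
induced dissociation.

Fragment ions are matched to experimental peaks within a ppm tolerance and
candidates are scored with the intensity/mass-weighted peak sum popularized
by combinatorial fragmenters: Σ intensityⁿ·(m/z)ᵐ over matched peaks with
n = 0.6, m = 3, normalized so the best candidate in a set scores 1.0. This
re-implements the fragment-and-score idea; no parity with any particular
external scorer is implied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem

from .chem import Adduct, ElementalFormula, get_adduct, monoisotopic_mass, ppm_error
from .elements import H_ATOM_MASS

__all__ = [
    "Ms2Spectrum",
    "Fragment",
    "Ms2Annotation",
    "Ms2Score",
    "FragmentConfig",
    "generate_fragments",
    "annotate_spectrum",
    "score_ms2_candidate",
    "rank_ms2_candidates",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ms2Spectrum:
    """A centroided MS/MS spectrum with precursor metadata."""

    precursor_mz: float
    polarity: str
    peaks: tuple[tuple[float, float], ...]
    collision_energy: float = 30.0
    label: str = ""

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("peak intensities must be non-negative")
        object.__setattr__(self, "peaks", pk)
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass(frozen=True)
class Fragment:
    """A connected substructure with formula, mass and provenance.

    ``neutral_mass`` already includes the hydrogen-rearrangement shift:
    monoisotopic_mass(formula) + h_shift × m(H atom).
    """

    atom_subset: frozenset[int]
    formula: ElementalFormula
    neutral_mass: float
    bonds_broken: int
    h_shift: int

    def ion_mz(self, adduct: Adduct) -> float:
        return (self.neutral_mass + adduct.delta_mass) / abs(adduct.charge)


@dataclass(frozen=True)
class FragmentConfig:
    """Fragmenter knobs: cut budget per step, recursion depth, H window."""

    max_bond_breaks: int = 2
    max_tree_depth: int = 2
    h_shift_window: int = 2

    def __post_init__(self) -> None:
        if self.max_bond_breaks < 0 or self.max_tree_depth < 0:
            raise ValueError("bond-break and depth limits must be non-negative")


def _heavy_atom_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(), symbol=atom.GetSymbol(), n_h=atom.GetTotalNumHs()
        )
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def _subset_formula(g: nx.Graph, atoms: Iterable[int]) -> ElementalFormula:
    counts: dict[str, int] = {}
    n_h = 0
    for a in atoms:
        sym = g.nodes[a]["symbol"]
        counts[sym] = counts.get(sym, 0) + 1
        n_h += g.nodes[a]["n_h"]
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    return ElementalFormula(counts)


def _mol_from_input(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"could not parse structure from SMILES: {structure!r}")
    return mol


def generate_fragments(
    structure: str | Chem.Mol,
    max_bond_breaks: int = 2,
    max_tree_depth: int = 2,
    h_shift_window: int = 2,
) -> list[Fragment]:
    """Enumerate fragments of a structure by systematic bond disconnection.

    At each recursion level every current fragment is cut at each
    combination of 1..``max_bond_breaks`` of its heavy-atom bonds; the
    connected components of the cut graph become child fragments. Fragments
    are deduplicated by (formula, h_shift); the intact molecule is always
    included (h_shift 0, 0 breaks). With ``max_bond_breaks`` = 0 only the
    intact molecule is returned.
    """
    mol = _mol_from_input(structure)
    g = _heavy_atom_graph(mol)
    if g.number_of_nodes() == 0:
        raise ValueError("structure has no heavy atoms")
    if not nx.is_connected(g):
        raise ValueError("structure must be a single connected molecule")

    all_atoms = frozenset(g.nodes)
    # atom-subset -> fewest cumulative bonds broken to reach it
    best_breaks: dict[frozenset[int], int] = {all_atoms: 0}
    frontier = [all_atoms]
    for _ in range(max_tree_depth):
        if max_bond_breaks == 0:
            break
        next_frontier: list[frozenset[int]] = []
        for subset in frontier:
            sub = g.subgraph(subset)
            edges = list(sub.edges)
            parent_breaks = best_breaks[subset]
            for k in range(1, max_bond_breaks + 1):
                for cut in combinations(edges, k):
                    h = sub.copy()
                    h.remove_edges_from(cut)
                    comps = list(nx.connected_components(h))
                    if len(comps) == 1:
                        continue  # cut did not disconnect (ring bonds)
                    for comp in comps:
                        child = frozenset(comp)
                        nb = parent_breaks + k
                        if child not in best_breaks or nb < best_breaks[child]:
                            if child not in best_breaks:
                                next_frontier.append(child)
                            best_breaks[child] = nb
        frontier = next_frontier
        if not frontier:
            break

    out: list[Fragment] = []
    seen: set[tuple[str, int]] = set()
    for subset, breaks in sorted(
        best_breaks.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
    ):
        formula = _subset_formula(g, subset)
        base_mass = monoisotopic_mass(formula)
        shifts = (0,) if subset == all_atoms else range(-h_shift_window, h_shift_window + 1)
        for s in shifts:
            if formula["H"] + s < 0:
                continue
            key = (formula.hill(), s)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                Fragment(
                    atom_subset=subset,
                    formula=formula,
                    neutral_mass=base_mass + s * H_ATOM_MASS,
                    bonds_broken=breaks,
                    h_shift=s,
                )
            )
    return out


@dataclass(frozen=True)
class Ms2Annotation:
    """Per-peak fragment assignments: peak index → (fragment, ppm error)."""

    matches: Mapping[int, tuple[Fragment, float]]
    unmatched: tuple[int, ...]
    n_peaks: int


def annotate_spectrum(
    fragments: Sequence[Fragment],
    spectrum: Ms2Spectrum,
    tol_ppm: float = 30.0,
    adduct: Adduct | str | None = None,
) -> Ms2Annotation:
    """Match fragment ions to spectrum peaks within a ppm tolerance.

    Fragment ion m/z follows the adduct convention — [F−H]⁻ in negative
    mode, [F+H]⁺ in positive mode by default. Each peak takes at most one
    fragment: ties resolve by smallest |ppm|, then fewest bonds broken,
    then smallest |h_shift|.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adduct is None:
        adduct = "[M+H]+" if spectrum.polarity == "positive" else "[M-H]-"
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)

    matches: dict[int, tuple[Fragment, float]] = {}
    unmatched: list[int] = []
    ions = [(f.ion_mz(adduct), f) for f in fragments]
    for idx, (mz, _inten) in enumerate(spectrum.peaks):
        best: tuple[float, int, int, Fragment] | None = None
        for ion_mz, frag in ions:
            err = ppm_error(mz, ion_mz)
            if abs(err) > tol_ppm:
                continue
            key = (abs(err), frag.bonds_broken, abs(frag.h_shift))
            if best is None or key < (best[0], best[1], best[2]):
                best = (abs(err), frag.bonds_broken, abs(frag.h_shift), frag)
                signed = err
        if best is None:
            unmatched.append(idx)
        else:
            matches[idx] = (best[3], signed)
    return Ms2Annotation(matches=matches, unmatched=tuple(unmatched), n_peaks=len(spectrum.peaks))


def score_ms2_candidate(
    annotation: Ms2Annotation,
    spectrum: Ms2Spectrum,
    intensity_exp: float = 0.6,
    mz_exp: float = 3.0,
) -> float:
    """Raw candidate score: Σ over matched peaks of relᵢⁿ · (m/z)ᵐ.

    Intensities are normalized to base peak = 1 before weighting, so the
    score is invariant to overall intensity scaling. Zero when nothing
    matches.
    """
    if not spectrum.peaks:
        raise ValueError("spectrum must have at least one peak")
    base = spectrum.base_peak_intensity
    if base <= 0:
        return 0.0
    total = 0.0
    for idx in annotation.matches:
        mz, inten = spectrum.peaks[idx]
        total += (inten / base) ** intensity_exp * mz**mz_exp
    return total


@dataclass(frozen=True)
class Ms2Score:
    """Per-candidate MS² evidence: raw and max-normalized score plus rank."""

    candidate_label: str
    raw_score: float
    normalized_score: float
    rank: int
    n_matched: int = 0


def rank_ms2_candidates(
    candidates: Mapping[str, str | Chem.Mol],
    spectrum: Ms2Spectrum,
    tol_ppm: float = 30.0,
    adduct: Adduct | str | None = None,
    frag_cfg: FragmentConfig | None = None,
) -> list[Ms2Score]:
    """Fragment, annotate and score a labeled candidate set.

    Scores are normalized by the maximum raw score so the best candidate
    reports 1.0; sorted by normalized score descending, label ascending on
    ties, with dense 1-based ranks. If no candidate matches anything, all
    normalized scores are 0 and ranks follow label order (with a warning).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    cfg = frag_cfg or FragmentConfig()
    raws: dict[str, tuple[float, int]] = {}
    for label, structure in candidates.items():
        frags = generate_fragments(
            structure, cfg.max_bond_breaks, cfg.max_tree_depth, cfg.h_shift_window
        )
        ann = annotate_spectrum(frags, spectrum, tol_ppm, adduct)
        raws[label] = (score_ms2_candidate(ann, spectrum), len(ann.matches))

    max_raw = max(r for r, _ in raws.values())
    if max_raw <= 0:
        log.warning("no candidate matched any peak; all MS2 scores are zero")
        ordered = sorted(raws)
        return [
            Ms2Score(label, 0.0, 0.0, rank=i + 1, n_matched=0)
            for i, label in enumerate(ordered)
        ]

    rows = sorted(raws.items(), key=lambda kv: (-kv[1][0], kv[0]))
    out: list[Ms2Score] = []
    rank = 0
    prev = None
    for label, (raw, nm) in rows:
        norm = raw / max_raw
        if norm != prev:
            rank += 1
            prev = norm
        out.append(Ms2Score(label, raw, norm, rank, nm))
    return out
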