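"""Deterministic synthetic scenarios for exercising the whole workflow.

Real inputs to the toolkit — experimental HSQC/TOCSY peak lists, MS/MS
spectra, predicted chemical shifts for database candidate structures — come
from spectrometers and commercial predictors. This module fabricates
internally consistent stand-ins with the statistical structure the method
assumes, so every stage (formula inference, HSQC matching, fragmentation,
mixture deconvolution, evidence combination) can be tested end to end from
a seed, with a truth table to score the resulting rankings against.

The generative model, in brief:

* each simulated metabolite contributes one spin system: a handful of HSQC
  cross-peaks with ¹H shifts kept ≥ a minimum separation apart across
  metabolites, chained together by TOCSY cross-peaks;
* the "predicted" peak list of the true candidate is the truth plus i.i.d.
  Gaussian error per peak per dimension (σ_H, σ_C), emulating empirical
  shift-predictor error; decoy candidates are drawn uniformly over
  plausible shift ranges but kept ≥ 3σ_H away from every true ¹H shift so
  scenario difficulty is explicit;
* MS² spectra take a random subset of the true structure's own in-silico
  fragment ions plus uniform noise peaks;
* isotope envelopes are the simulated pattern of the true formula with
  multiplicative abundance noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chem import (
    Adduct,
    ElementalFormula,
    IsotopePattern,
    adduct_mz,
    get_adduct,
    isotope_pattern,
    parse_formula,
)
from .formula import MassFeature
from .fragment import FragmentConfig, Ms2Spectrum, generate_fragments
from .hsqc import HsqcPeak, HsqcPeakList
from .mixture import TocsyPeak, group_peaks_by_connectivity

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "FeatureScenario",
    "METABOLITE_LIBRARY",
    "perturb_hsqc",
    "simulate_ms2",
    "simulate_envelope",
    "random_plausible_formula",
    "build_scenario",
]

log = logging.getLogger(__name__)

#: small built-in pool of real metabolite structures (name → SMILES) used as
#: true/decoy structures; chemical shifts are always synthesized, not looked up
METABOLITE_LIBRARY: dict[str, str] = {
    "valine": "CC(C)C(N)C(=O)O",
    "methionine": "CSCCC(N)C(=O)O",
    "glutamine": "NC(=O)CCC(N)C(=O)O",
    "leucine": "CC(C)CC(N)C(=O)O",
    "isoleucine": "CCC(C)C(N)C(=O)O",
    "proline": "OC(=O)C1CCCN1",
    "phenylalanine": "NC(Cc1ccccc1)C(=O)O",
    "nicotinate": "OC(=O)c1cccnc1",
    "thymidine": "Cc1cn(C2CC(O)C(CO)O2)c(=O)[nH]c1=O",
    "pantothenate": "CC(C)(CO)C(O)C(=O)NCCC(=O)O",
}

_H_LO, _H_HI = 0.5, 9.5
_C_LO, _C_HI = 10.0, 145.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the scenario generator; same seed ⇒ identical scenario."""

    n_features: int = 10
    decoys_per_feature: int = 20
    sigma_h: float = 0.05
    sigma_c: float = 0.5
    ms2_noise_peaks: int = 3
    envelope_noise: float = 0.05
    seed: int = 0
    decoy_min_sep_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("scenario needs at least one feature")
        if self.decoys_per_feature < 0 or self.ms2_noise_peaks < 0:
            raise ValueError("counts must be non-negative")
        if self.sigma_h < 0 or self.sigma_c < 0 or self.envelope_noise < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class FeatureScenario:
    """Everything generated for a single LC-MS feature."""

    feature_id: str
    metabolite: str
    smiles: str
    formula: ElementalFormula
    mass_feature: MassFeature
    ms2: Ms2Spectrum
    true_peaks: tuple[HsqcPeak, ...]
    candidates: tuple[HsqcPeakList, ...]
    candidate_structures: Mapping[str, str]
    true_candidate_label: str


@dataclass(frozen=True)
class Scenario:
    """A complete mixture scenario plus its truth table."""

    config: ScenarioConfig
    features: tuple[FeatureScenario, ...]
    experimental_hsqc: HsqcPeakList
    tocsy: tuple[TocsyPeak, ...]
    #: feature_id -> (true candidate label, true group id after deconvolution)
    truth: Mapping[str, tuple[str, str]]


def perturb_hsqc(
    true_peaks: HsqcPeakList, sigma_h: float, sigma_c: float, seed: int
) -> HsqcPeakList:
    """Add i.i.d. Gaussian error per peak per dimension; seed-reproducible.

    Emulates an empirical chemical-shift predictor whose errors are a few
    hundredths of a ppm in ¹H and a few tenths in ¹³C. Returns a
    predicted-kind list with the same label.
    """
    if sigma_h < 0 or sigma_c < 0:
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    peaks = []
    for p in true_peaks.peaks:
        dh = rng.normal(0.0, sigma_h) if sigma_h else 0.0
        dc = rng.normal(0.0, sigma_c) if sigma_c else 0.0
        peaks.append(HsqcPeak(p.h_shift + dh, p.c_shift + dc, p.intensity))
    return HsqcPeakList(label=true_peaks.label, kind="predicted", peaks=tuple(peaks))


def simulate_ms2(
    structure: str | Chem.Mol,
    frag_cfg: FragmentConfig | None = None,
    n_noise_peaks: int = 0,
    seed: int = 0,
    adduct: Adduct | str = "[M+H]+",
    subset_fraction: float = 0.8,
    label: str = "",
) -> Ms2Spectrum:
    """Simulate an MS/MS spectrum from a structure's own fragment ions.

    Takes a random subset (at least half, controlled by
    ``subset_fraction`` ∈ [0.5, 1]) of the in-silico fragment ions as peaks
    with random intensities, plus ``n_noise_peaks`` uniform-random noise
    peaks below the precursor. A structure with no proper fragments yields
    a precursor-only spectrum with a warning.
    """
    if not 0.5 <= subset_fraction <= 1.0:
        raise ValueError("subset_fraction must be in [0.5, 1]")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    cfg = frag_cfg or FragmentConfig()
    rng = np.random.default_rng(seed)
    frags = generate_fragments(
        structure, cfg.max_bond_breaks, cfg.max_tree_depth, cfg.h_shift_window
    )
    precursor = max(f.ion_mz(adduct) for f in frags if f.bonds_broken == 0)
    proper = sorted({round(f.ion_mz(adduct), 6) for f in frags if f.bonds_broken > 0})
    proper = [mz for mz in proper if mz > 40.0]
    peaks: list[tuple[float, float]] = []
    if not proper:
        warnings.warn("structure produced no proper fragments; precursor-only spectrum")
        peaks.append((precursor, 1.0))
    else:
        n_keep = max(1, int(round(subset_fraction * len(proper))))
        keep = rng.choice(len(proper), size=n_keep, replace=False)
        for idx in sorted(keep):
            peaks.append((proper[idx], float(rng.uniform(0.2, 1.0))))
    for _ in range(n_noise_peaks):
        peaks.append(
            (float(rng.uniform(45.0, precursor)), float(rng.uniform(0.01, 0.1)))
        )
    return Ms2Spectrum(
        precursor_mz=precursor,
        polarity=adduct.polarity,
        peaks=tuple(peaks),
        label=label,
    )


def simulate_envelope(
    formula: ElementalFormula | str,
    adduct: Adduct | str,
    noise: float = 0.0,
    seed: int = 0,
    n_isotopologues: int = 3,
) -> IsotopePattern:
    """Isotope envelope of an ionized formula with multiplicative noise.

    Pattern masses are shifted to the ion m/z scale through the adduct;
    abundances are multiplied by (1 + noise·ε), ε ~ U(−1, 1), then
    re-normalized to base peak = 1.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    rng = np.random.default_rng(seed)
    theo = isotope_pattern(formula, n_isotopologues)
    pairs = []
    for m, a in theo.isotopologues:
        noisy = a * (1.0 + noise * rng.uniform(-1.0, 1.0)) if noise else a
        pairs.append(((m + adduct.delta_mass) / abs(adduct.charge), max(noisy, 1e-12)))
    return IsotopePattern.from_pairs(pairs)


def random_plausible_formula(rng: np.random.Generator) -> ElementalFormula:
    """A random CHNO(S) formula with a chemically plausible H count.

    Heteroatom counts are modest and the hydrogen count is drawn so the
    ring-double-bond equivalent is a non-negative integer — the shape of
    formulas the plausibility filter keeps.
    """
    while True:
        c = int(rng.integers(4, 21))
        n = int(rng.integers(0, 4))
        o = int(rng.integers(0, 9))
        s = int(rng.integers(0, 3))
        max_rdbe = c  # keep saturation realistic
        r = int(rng.integers(0, min(max_rdbe, 8) + 1))
        h = 2 * c + 2 + n - 2 * r
        if h < 1:
            continue
        counts = {"C": c, "H": h}
        if n:
            counts["N"] = n
        if o:
            counts["O"] = o
        if s:
            counts["S"] = s
        f = ElementalFormula(counts)
        if 80.0 <= f.mass <= 500.0:
            return f


def _spin_system_shifts(
    rng: np.random.Generator, n_peaks: int, taken_h: list[float], min_sep: float
) -> list[HsqcPeak]:
    peaks = []
    for _ in range(n_peaks):
        for _attempt in range(10_000):
            h = float(rng.uniform(_H_LO, _H_HI))
            if all(abs(h - t) >= min_sep for t in taken_h):
                break
        else:  # pragma: no cover - only reachable with absurd densities
            raise RuntimeError("could not place spin-system peaks with required separation")
        taken_h.append(h)
        peaks.append(HsqcPeak(h, float(rng.uniform(_C_LO, _C_HI))))
    return peaks


def _n_ch_groups(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return sum(
        1 for a in mol.GetAtoms() if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    )


def build_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate a complete, internally consistent mixture scenario.

    Metabolites are drawn (cyclically) from the built-in library; each
    contributes a spin system to a shared experimental HSQC, a TOCSY chain
    linking its peaks, a mass feature with noisy isotope envelope, a
    simulated MS² spectrum, and a candidate set of one perturbed true
    prediction plus uniform decoys. Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(METABOLITE_LIBRARY)
    chosen = [names[i % len(names)] for i in range(cfg.n_features)]

    # lay out all spin systems first so cross-feature ¹H separation holds
    taken_h: list[float] = []
    min_sep = max(0.06, 2.0 * cfg.sigma_h)
    per_feature_peaks: list[list[HsqcPeak]] = []
    for name in chosen:
        n_peaks = max(2, min(_n_ch_groups(METABOLITE_LIBRARY[name]), 6))
        per_feature_peaks.append(
            _spin_system_shifts(rng, n_peaks, taken_h, min_sep)
        )

    all_true_h = [p.h_shift for peaks in per_feature_peaks for p in peaks]
    exp_peaks = tuple(p for peaks in per_feature_peaks for p in peaks)
    experimental = HsqcPeakList(label="mixture", kind="experimental", peaks=exp_peaks)

    tocsy: list[TocsyPeak] = []
    for peaks in per_feature_peaks:
        ordered = sorted(peaks, key=lambda p: p.h_shift)
        for a, b in zip(ordered, ordered[1:]):
            tocsy.append(TocsyPeak(a.h_shift, b.h_shift))

    groups = group_peaks_by_connectivity(experimental, tocsy)

    def group_of(peak: HsqcPeak) -> str:
        for grp in groups:
            if peak in grp.peaks.peaks:
                return grp.group_id
        raise AssertionError("peak missing from deconvolution")  # pragma: no cover

    decoy_sep = cfg.decoy_min_sep_sigma * cfg.sigma_h
    features: list[FeatureScenario] = []
    truth: dict[str, tuple[str, str]] = {}
    for i, (name, peaks) in enumerate(zip(chosen, per_feature_peaks)):
        fid = f"F{i + 1}"
        smiles = METABOLITE_LIBRARY[name]
        formula = parse_formula(
            rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(smiles)).rstrip("+-")
        )
        adduct = get_adduct("[M+H]+")
        sub = int(rng.integers(0, 2**31 - 1))
        envelope = simulate_envelope(formula, adduct, cfg.envelope_noise, seed=sub)
        feature = MassFeature(
            mz=adduct_mz(formula, adduct),
            polarity="positive",
            adduct=adduct,
            isotope_envelope=envelope,
            label=fid,
        )
        ms2 = simulate_ms2(
            smiles,
            n_noise_peaks=cfg.ms2_noise_peaks,
            seed=int(rng.integers(0, 2**31 - 1)),
            adduct=adduct,
            label=fid,
        )
        true_label = f"{fid}/{name}"
        true_list = HsqcPeakList(label=true_label, kind="experimental", peaks=tuple(peaks))
        predicted_true = perturb_hsqc(
            true_list, cfg.sigma_h, cfg.sigma_c, seed=int(rng.integers(0, 2**31 - 1))
        )
        cands = [predicted_true]
        for d in range(cfg.decoys_per_feature):
            n_dec = len(peaks)
            dec_peaks = []
            for _ in range(n_dec):
                for _attempt in range(10_000):
                    h = float(rng.uniform(_H_LO, _H_HI))
                    if all(abs(h - t) >= decoy_sep for t in all_true_h):
                        break
                dec_peaks.append(HsqcPeak(h, float(rng.uniform(_C_LO, _C_HI))))
            cands.append(
                HsqcPeakList(
                    label=f"{fid}/decoy{d + 1}", kind="predicted", peaks=tuple(dec_peaks)
                )
            )
        # MS2 candidate structures: truth plus mass-distinct library decoys
        structures = {true_label: smiles}
        for other, osmi in METABOLITE_LIBRARY.items():
            if other == name:
                continue
            oform = rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(osmi))
            if oform.rstrip("+-") == formula.hill():
                continue
            structures[f"{fid}/{other}"] = osmi
        gid = group_of(peaks[0])
        features.append(
            FeatureScenario(
                feature_id=fid,
                metabolite=name,
                smiles=smiles,
                formula=formula,
                mass_feature=feature,
                ms2=ms2,
                true_peaks=tuple(peaks),
                candidates=tuple(cands),
                candidate_structures=structures,
                true_candidate_label=true_label,
            )
        )
        truth[fid] = (true_label, gid)

    return Scenario(
        config=cfg,
        features=tuple(features),
        experimental_hsqc=experimental,
        tocsy=tuple(tocsy),
        truth=truth,
    )
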