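# Methods

This note documents the models, parameter choices and numerical
conventions behind `hybridrank`, and what the synthetic benchmarks do and
do not demonstrate.

## Mass arithmetic

Atomic masses and natural isotope abundances are pinned to a bundled
IUPAC/CIAAW table (`hybridrank/elements.py`) rather than taken from a
dependency, so mass arithmetic never drifts with a library upgrade.
Monoisotopic mass uses the *most abundant* isotope of each element.
Protonation and deprotonation add or remove a bare proton
(1.007 276 46 Da), not a hydrogen atom: the electron stays with the
neutral. Reported integer ppm errors are the **floor** of the absolute
signed error, (obs − theo)/theo × 10⁶. This floor convention (rather than
round-half-up) is what reproduces the published integer mass-accuracy
values for all ten reference metabolites the package's acceptance checks
use (e.g. a 5.51 ppm error reported as 5, a 0.85 ppm error as 0); it is a
documented inference, overridable by using the signed `ppm_error`
directly.

Isotope envelopes are simulated by per-element single-atom distributions
raised to their atom counts via repeated convolution (square-and-multiply)
and multiplied across elements. Aggregation is at **nominal-mass
resolution**: each M+k bin carries the abundance-weighted mean exact mass.
This matches what a Q-TOF resolves; isotope fine structure is out of
scope. A tail cutoff of 1e-12 relative abundance keeps repeated
convolution linear; the unit tests verify agreement with exhaustive
isotopologue enumeration to 1e-9 for small molecules.

## Formula inference

Enumeration is a bounded depth-first count over elements ordered by
decreasing mass with branch-and-bound pruning. It is provably complete
within the bounds and fast below ~1 kDa, so no money-changing
decomposition is needed. Default bounds are CHNOPS with per-element maxima
scaled to the target mass; a candidate cap (200 000) turns pathological
windows into an explicit error instead of a stall.

The isotope-fit statistic is a normalized L1 distance,
score = 1 − Σₖ|obsₖ − theoₖ|/Σₖ theoₖ over the first K nominal-mass bins
(K = 3 by default; missing observed bins count as zero), clipped to
[0, 1]. It was chosen for boundedness and the absence of free parameters —
scores are comparable across candidate sets — and is pluggable. Candidates
with negative or fractional RDBE (general valence form
1 + Σ nᵢ(vᵢ − 2)/2) are dropped by default; fractional RDBE marks an
odd-electron composition that cannot be a neutral closed-shell molecule.
The filter is a flag, not a constant. Neutral-mass recovery always goes
through the *declared* adduct; unknown adduct names are an error, never a
guess.

Note a practical asymmetry: with a well-calibrated m/z a 5–10 ppm window
suffices, but real unknowns can sit 15–20 ppm off on some LC
column/calibration combinations, in which case the window must be opened
to 30 ppm and the isotope envelope does the narrowing.

## HSQC matching

The distance between a predicted and an experimental cross-peak is
weighted Euclidean, √((w_H Δδ¹H)² + (w_C Δδ¹³C)²), with defaults
w_H = 10, w_C = 1 — the ¹H dimension disperses over ~10 ppm versus
~200 ppm for ¹³C, so equal nominal weights would let carbon dominate.
City-block distance differs only in degenerate tie cases; Euclidean is the
default and the ranking is invariant to scaling both weights.

Assignment is one-to-one: an experimental peak may serve at most one
predicted peak, which prevents a degenerate candidate from collapsing all
its predictions onto a single intense experimental peak. Pairs outside the
per-dimension cutoffs (Δδ¹H ≤ 0.5 ppm, Δδ¹³C ≤ 5 ppm by default —
permissive relative to typical empirical-predictor mean errors of
0.1–0.3 ppm ¹H / 1–3 ppm ¹³C, and config-exposed) are never formed. The
default pairing is greedy nearest-first over the full distance matrix; a
globally optimal minimum-cost bipartite assignment
(`MatchConfig(assignment="optimal")`, via the Hungarian algorithm) is a
config switch. On uniform random peak lists over typical shift ranges the
two agree (asserted against a brute-force permutation oracle); they can
differ when many peaks crowd within one cutoff radius, where greedy may
match one peak fewer — the optimal switch exists for exactly that regime.

The matching ratio divides by the **predicted** peak count (5 matched of 6
predicted → 0.8333, reported as 0.83 at 2 decimals). Candidates are ranked
lexicographically by (matching ratio desc, weighted mean distance asc,
label asc); ranks are dense and 1-based, and a candidate with no matches
carries NaN mean errors and sorts last. The composite order (ratio before
distance) is the default; the reverse is available because the two
criteria are stated jointly in the field without a fixed precedence.

## In-silico fragmentation and MS² scoring

Fragmentation operates on the heavy-atom graph: at each recursion level
every current fragment is cut at each combination of up to
`max_bond_breaks` bonds, and connected components of the cut graph become
child fragments. Defaults are 2 breaks per step and depth 2 — enough to
open a ring (which needs two cuts; a single cut of benzene produces
nothing, since every ring bond is a non-bridge) while keeping desk-scale
runtime. Each fragment keeps the hydrogens attached to its atoms in the
parent and is emitted with hydrogen-rearrangement variants of −2…+2 H
(mass shifted by the H-atom mass), deduplicated by (formula, h-shift).
Fragment ions follow the adduct convention, [F−H]⁻ in negative mode and
[F+H]⁺ in positive mode by default.

Peak annotation assigns each experimental peak at most one fragment within
the ppm tolerance (default 30 ppm), preferring smallest |ppm|, then fewest
bonds broken, then smallest |h-shift|. The candidate score is
Σ intensity^0.6 × (m/z)³ over matched peaks with intensities normalized to
base peak 1 — the classical combinatorial-fragmenter weighting that
rewards explaining heavy, intense peaks; both exponents are config values.
Scores are normalized by the set maximum so the best candidate reports
1.0. This is a re-implementation of the fragment-and-score *idea*; parity
with any specific external scorer's numbers is not claimed or tested.

## Mixture deconvolution and evidence combination

HSQC peaks are grouped into spin systems by building a graph whose edges
come from TOCSY cross-peaks: two HSQC peaks connect when a TOCSY peak's
(δ¹H, δ¹H) pair matches their proton shifts within 0.02 ppm (either
orientation); connected components are the groups, with deterministic ids
ordered by each group's lowest ¹H shift. HMBC-derived connectivity can be
supplied as extra edges in the same form; TOCSY-only is the default. The
output is asserted to be a partition on every call.

The pairwise stage scores every candidate of every feature against every
group with the same matcher and orders all pairs globally; ties break by
candidate label then group id, so shuffling input order never changes
results. NMR and MS² ranks combine by **rank product** — scale-free and
order-based, appropriate since the two scores live on incomparable scales
— with missing candidates imputed at worst-rank + 1 rather than dropped.
The raw two-rank table is always emitted so users can apply their own
rule. A candidate ranked first on both axes is necessarily first combined.

## Synthetic scenarios

The generator fabricates internally consistent inputs with the statistical
structure the method assumes; defaults mirror a ten-metabolite mixture
benchmark: 10 features, 20 decoy candidates per feature, predictor noise
σ_H = 0.05 ppm and σ_C = 0.5 ppm (the magnitude of empirical HSQC
predictor errors), 3 MS² noise peaks, 5% multiplicative isotope-envelope
noise.

Structures and formulas come from a built-in pool of ten real metabolites,
but chemical shifts are *synthesized*: each feature's spin system is drawn
uniformly over plausible ranges (¹H 0.5–9.5 ppm, ¹³C 10–145 ppm) with a
minimum cross-feature ¹H separation of max(0.06 ppm, 2σ_H). Literature
shifts were deliberately not used as truth: real metabolites share
near-degenerate methyl ¹H shifts (differences of ~0.01 ppm), which would
merge TOCSY spin systems and make the truth table ill-defined — real
mixtures genuinely have this ambiguity, and the benchmark is meant to
measure ranking behaviour under controlled difficulty, not peak-overlap
resolution. Decoy peak lists keep ≥ 3σ_H ¹H separation from every true
peak so their difficulty is explicit. The "predicted" list of the true
candidate is the truth plus i.i.d. Gaussian error per peak per dimension;
the unit tests verify the |error| distribution against its half-normal
mean at n = 10⁴. MS² spectra take a random ≥ 50% subset of the true
structure's own fragment ions with random intensities plus uniform noise
peaks.

Consequently, passing benchmarks show that the pipeline recovers planted
truth under the assumed noise model — they do not show robustness to
predictor bias (systematic shift offsets), peak overlap between spin
systems, missing experimental peaks, or fragmentation chemistry the
bond-disconnection model cannot produce.

## Numerical and I/O conventions

All output writers are deterministic (stable sort, fixed precision:
shifts and scores 4 decimals, ratios 2, masses 6). Scenario files and MGF
spectra are written at full float precision, and peak tables are parsed
back through Python's `float()` (not the CSV reader's approximate parser),
so a write→read round trip reproduces in-memory objects exactly.
Problem sizes in the shipped checks — 100 self-match trials, 200
assignment-oracle instances, 50 fragmenter-oracle molecules, 20
formula-recovery features, a 10-feature mixture with MS² verified on 4
features — were chosen so the whole suite completes in about a minute on
one CPU while keeping Monte-Carlo noise well below the asserted margins.

## Known limitations

* Charge states beyond |z| = 1 are handled only arithmetically; multiply
  charged envelopes are not modelled.
* Isotope patterns are nominal-mass aggregates; no fine structure.
* The fragmenter has no bond-dissociation-energy term and no
  collision-energy-dependent intensity model; scores are rank evidence,
  not spectral predictions.
* HSQC matching treats peak lists as unordered point sets; intensities are
  carried but unused by the default score.
* Chemical-shift prediction itself is out of scope — predicted peak lists
  are an input.
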