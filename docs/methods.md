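# Methods

## Lipid model

A lipid class is defined by the elemental composition of its species at
zero radyl carbons and zero double bonds, the number of radyl positions
(1–3), carbon and double-bond ranges, allowed ether modifiers, and — for
sphingolipids — the hydroxylation tag of the sphingoid base (`d` =
dihydroxy). Species compositions follow the increment scheme
`base + nC·CH₂ − nDB·H₂`. The scheme reproduces structural assembly
exactly: the test suite builds reference lipids atom-by-atom from glycerol,
fatty acids, phosphocholine/phosphoethanolamine and sphingosine and checks
equality of compositions, with pyteomics as an independent mass oracle.

Ether conventions. One radyl position may carry an ether linkage instead of
an ester: alkyl (`-O`) substitutes −O +2H relative to the diacyl species;
alkenyl (`-P`, plasmalogen) additionally carries the vinyl double bond, a
net −O. Consequently a `P` species with *n* double bonds is exactly
isobaric with the `O` species with *n*+1 — the origin of the primed
`PC(O-34:1)'` notation used when chromatography cannot distinguish them.

Sphingolipids are collapsed to (total carbons, total double bonds) over
the sphingoid base plus N-acyl chain, so `SM(d18:1/12:0)` and `SM(d30:1)`
are the same composition; per-chain standard names are parsed and
canonicalized to the collapsed form.

Atomic masses are most-abundant-isotope masses stored in one bundled
reference table; the electron mass enters ion m/z as
`(M + Δm − z·mₑ)/|z|`. Protonation therefore adds the hydrogen-atom mass
minus the electron mass, which differs from the bare-proton mass only by
the hydrogen binding energy (~1.5·10⁻⁸ Da), far below any instrument
tolerance.

Default adducts are [M+H]⁺ and [M+NH₄]⁺ in positive mode and [M−H]⁻ and
[M+HCOO]⁻ in negative mode, matching mobile phases containing ammonia and
formic acid. The bundled class-definition file ships 17 classes with
default carbon ranges 24–44 (diacyl phospholipids), 12–22 (lyso), 36–60
(TG), 26–44 (sphingolipids) etc.; ranges and the adduct set are
user-overridable, since neither is dictated by the instrument setup.

## Annotation

Candidates for a feature are all (species, adduct) ions of matching
polarity within the ppm tolerance (default 5 ppm, Orbitrap-class accuracy)
whose class retention window — when one is configured for the feature's
chromatography mode — contains the feature's retention time. The winner is
the candidate with smallest |ppm error|; exact isobars are collapsed by the
ether rule above or, failing that, broken lexicographically and flagged
`multi-candidate` so downstream users can audit them. Matching is
order-independent and deterministic. Scan-range filtering (default m/z
150–2000) treats both bounds as inclusive.

Retention windows are per (class, mode), with optional ether-specific
overrides keyed as e.g. `PC(O)`. Windows are essential, not cosmetic: the
expanded database contains exact cross-class isobars (BMP/PG share one
formula; PC(x:y) ≡ PE(x+3:y); ammoniated PA ≡ protonated PC), which only
chromatography can separate. The bundled default windows give each class a
disjoint window in both modes — an idealization of "relative retention
time" identification; they are a configuration input, not measured values.

## Semiquantification

`abundance(species, sample) = area / area(class standard, sample, mode) ×
amount(standard)`, in arbitrary units (nmol-equivalents). The bundled
standard table lists the 18 spiked standards with their amounts; exactly
one per class and mode acts as the class reference (`role =
class_standard`), the remaining spikes (the second ceramide and sphingosine
standards) are kept as `auxiliary` rows. The two printed BMP amounts are
interpreted as mode-specific: 0.2 nmol in normal phase, 2.5 nmol in
reversed phase — the assignment is a configuration default, switchable in
the table. Ether PC/PE species are normalized against the diacyl PC/PE
standards, as no dedicated ether standards exist.

Species without any dedicated class standard (here: free fatty acids) form
the secondary tier, normalized against the PE standard of their acquisition
mode. Secondary abundances are excluded from species-level statistics and
participate only in class-level aggregation, where a shared reference
cancels out.

Missing or non-positive standard peaks produce flagged NaN cells and an
explicit problem record; nothing is imputed or silently dropped. If one
species is observed in several acquisition modes its areas are normalized
per mode against that mode's standard.

## Statistics

* Two-group comparisons use the two-sided Wilcoxon rank-sum test: exact
  null distribution for combined sample sizes ≤ 25 without ties (verified
  against brute-force enumeration for all sizes with n+m ≤ 12), otherwise
  the normal approximation with continuity and tie correction. Degenerate
  all-identical input returns p = 1 with zero fold change.
* Species-level fold change is log₂ of the ratio of group means of
  normalized abundances (switchable to medians). Non-positive group means
  make the fold change undefined; such species are excluded from volcano
  classification with a logged count.
* Benjamini–Hochberg correction is applied across all tested primary-tier
  species of the dataset; significance thresholds are adjusted p < 0.05 at
  the species level and raw p < 0.05 at the class level.
* Regulation fractions (up/down/unchanged) are integer percentages by the
  largest-remainder rule, so they always sum to exactly 100.
* Class aggregates are per-participant sums over all species of the class,
  both tiers included. Paired admission-vs-recovery comparisons use the
  two-sided Wilcoxon signed-rank test on subject-matched pairs — the
  standard reading of a "paired Wilcoxon" design.
* PCA standardizes each species to zero mean and unit variance across the
  compared samples (zero-variance species dropped with a log entry), then
  decomposes; PC1 is oriented so the case group's mean score is ≥ the
  reference group's, making the sign convention reproducible. Group
  separation is tested by the rank-sum test on PC1 coordinates.
* Saturation categories follow the double-bond total: 0 = saturated, 1 =
  monounsaturated, ≥ 2 = polyunsaturated-containing. Because a
  two-double-bond species could in principle carry two monounsaturated
  chains, the grid also carries a `pufa_guaranteed` flag that is true only
  when the double-bond count forces a polyunsaturated chain: > 4 for the
  three-chain TG class (the stated rule, implemented verbatim), > 2 for
  two-chain classes, ≥ 2 for single-chain species.
* Pathway scores z-score each gene across samples (sample standard
  deviation, ddof 1) and average over the pathway's genes per sample;
  missing and zero-variance genes are skipped with a log entry.

## Synthetic cohorts

The generator draws species abundances from a lognormal model:
`exp(μᵢ + ln mᵢg + σ·ε)` with per-species baseline log-mean
μᵢ ~ N(0, 1), group multiplier mᵢg and σ set by a 30% coefficient of
variation — strictly positive and heavy-tailed, like MS intensities. The
multiplier scales median and mean alike, so a planted multiplier of 2 is a
planted species-level log₂ fold change of exactly 1.

Group sizes default to the study design (25 / 48 / 33, with the recovery
group resampling the first 33 admission subjects for paired analyses). Two
default profiles mirror the qualitative direction of the study system;
magnitudes are honest inventions chosen once as plausible effect sizes:

* monocyte-like (~215 species): PC 0.8×, PE 0.8×, SM 0.7×, FA 0.7× at
  admission; fully resolved at recovery (recovery multiplier 1).
* neutrophil-like (~290 species): BMP 2.5×, PA 2.0×, DG 1.5×, LPE 1.5×,
  PC 1.4×, PE 1.4×, FA 1.5×, SM 0.8×, SPH 0.7×; TG saturation-dependent,
  0.8 × 1.15^nDB (saturated species down, polyunsaturated up, so the class
  direction is "mixed" in the ground truth); partial resolution at
  recovery (multiplier^0.5).

Sparse species-level effects (default: 5% of species, log₂FC ±1) are
planted only in classes without a class-wide shift, keeping class-level
ground truth unambiguous. Desk-scale rosters (~200/~300 species rather than
the hundreds of a full cellular lipidome) keep grid-search and replicate
studies fast; rosters, multipliers and noise are all configuration. Roster
grids deliberately avoid the internal-standard species (14:0/d18:1-12:0
chains), mirroring the choice of standards outside the endogenous range.

Raw-feature emission places each species at its theoretical adduct m/z
with uniform ppm jitter (default ±2 ppm), in the middle of its class
retention window, with area = true abundance × class response ×
mean-one lognormal noise. Internal-standard peaks are emitted per sample
with area = spiked amount × class response, so with zero noise the
simulate → annotate → quantify pipeline is the identity on true abundances
(verified to float precision). Decoy features are placed at least four
5-ppm tolerances from every database ion.

What the generator does **not** emulate: chromatographic peak shapes,
batch and drift effects, missingness, correlated species (species are
independent given their class multiplier), ion suppression, isotope
patterns, or in-source fragmentation. Passing tests therefore demonstrate
correctness of the computations under the stated statistical model, not
robustness to those real-data phenomena.

## Numerical choices and limitations

* All randomness flows from a single `numpy` Generator per simulation;
  identical configurations (including seed) give bit-identical outputs.
* Exact isobars in annotation are detected at 10⁻⁴ ppm; mass arithmetic is
  reproducible to 10⁻⁹ Da.
* Ties across classes in annotation resolve lexicographically and are
  flagged rather than hidden; unassigned features, rejected rows and
  skipped species are always reported.
* Class-level tests are unadjusted by design (few classes, following the
  workflow's convention); interpret marginal class p-values accordingly.
* The fold-change-of-means estimator is slightly biased at very small
  sample sizes; at the cohort's group sizes the bias is below 0.01 log₂
  units (bounded at < 0.1 in the acceptance suite).
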