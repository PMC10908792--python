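# Methods

This note documents the models, rules and numerical choices behind the
package, in the order the pipeline applies them, and states what the
synthetic cohort does and does not emulate.

## Mass arithmetic and annotation

Element masses and isotope abundances come from the NIST table shipped
with pyteomics. Ion m/z for a neutral composition M and an adduct with
neutral mass change Δm and charge z is (M + Δm − z·mₑ)/|z|; the electron
mass (5.49·10⁻⁴ Da) is kept because it exceeds 1 ppm below ~550 m/z, the
region where most breath metabolites fall. Only singly charged species
are considered — direct-infusion ESI of small molecules produces
essentially no multiply charged ions in the 65–1500 m/z range. The adduct
set is [M+H]⁺/[M+Na]⁺/[M+K]⁺ in positive and [M−H]⁻/[M+Cl]⁻ in negative
mode: sodium, potassium and chloride attachment plus (de)protonation as
the implicit base ionisation, without which ESI produces no ions at all.

Recalibration fits a linear map (offset + slope) from observed to
theoretical m/z over calibrants matched within 5 ppm, falling back to a
pure offset for a single match. The correction is idempotent to numerical
precision because a second fit sees residuals already at the noise floor.

**Isotopic fine structure.** Isotopologue probabilities are an exhaustive
multinomial expansion over natural abundances; peaks closer than the
FWHM implied by the resolving power (m/R, default R = 488 000) are merged
into abundance-weighted centroids, and peaks below a relative-abundance
floor are dropped. The fit score between an observed and a theoretical
pattern is

  score = 1000 · √( Σᵢ wᵢ dᵢ² / Σᵢ wᵢ ),  wᵢ = √aᵢ,

where dᵢ is the relative deviation of the observed abundance of
theoretical peak i (matched within 2 ppm) and dᵢ = 1 for an expected peak
with no observed counterpart. The √a weighting makes strong satellites
dominate while keeping a missing satellite expensive: a uniform ~30%
abundance error scores near the acceptance cut-off of 300, and a
spectrum with *no* fine structure at all scores far above it. The cut-off
mirrors the customary vendor threshold, but the vendor metric has no
published formula; ours is an analogue, not a clone, and the threshold is
configuration, never hard-coded.

**Evidence-aware gating.** Fine structure is only *demanded* where it is
measurable. A feature whose mean intensity is below
`score_min_intensity` (default 10⁸ counts, i.e. 100× the detection limit)
cannot show satellites at the 5% theoretical floor above the detection
limit, so such features are annotated on mass accuracy alone (score
recorded as NaN). Without this rule every genuine low-abundance
metabolite would be vetoed for "missing" satellites that are physically
unobservable.

Ties between reference records with the same formula are all kept as
hits; downstream metadata takes the first-listed record, the convention
of common annotation suites, and the putative identity is exactly that —
putative. Unannotated features are retained, keyed by their binned m/z.

## Feature tables and normalization

Peaks from all acquisitions of one (mode, method) group are pooled,
sorted, and split into bins wherever the gap to the previous peak exceeds
the ppm tolerance (1 ppm default); a bin becomes a feature with
intensity-weighted mean m/z. After annotation, unannotated features
sitting at an annotated feature's isotopologue positions with lower total
intensity are removed (de-isotoping).

PQN: the reference spectrum is the feature-wise median over pooled-QC
columns (the QCs are a physical pool of all samples, so their median is
the natural dilution anchor); each sample is divided by the median of its
value/reference quotients over shared nonzero features. If a sample is an
exact scalar multiple of the reference the factor is recovered exactly.
Batch correction divides out the ratio of each batch's QC median to the
global QC median; a batch without QCs falls back to its sample median
with a warning. Median normalization rescales each sample's nonzero
median to the global median of sample medians and is idempotent.

Mode merging operates per formula: the ionisation mode that detected the
metabolite in more samples wins; on a tie, the larger summed intensity;
on an exact double tie, positive mode (an arbitrary but fixed
convention). Deduplication keeps, per formula, the row with the largest
total intensity — this collapses the 95–300 m/z overlap of the two
mass-range methods and any residual multi-adduct rows.

Replicate consensus implements the 2-of-3 rule: a metabolite counts for a
subject only when detected in ≥ 2 of the 3 breath replicates, and the
retained value is the mean of the *detected* intensities only — zeros are
absences, not measurements. Prevalence filters use a ceiling rule at the
subject level (ceil(fraction × n_subjects); with 101 subjects the 15%
filter requires 16), applied as two configured passes (5% at table
assembly, 15% before statistics). Zeros are then imputed at LOD/5
(10⁶/5 = 2·10⁵ counts), and the data are log₁₀-transformed and
Pareto-scaled (centre, divide by √sd; a zero-variance feature stays
centred at 0 rather than dividing by zero). The log base is
configurable; 10 is the default.

## Statistics

*Volcano*: Welch two-sample t-test on log-transformed intensities (the
t-statistic is invariant to the per-feature affine Pareto scaling),
Benjamini–Hochberg FDR, significance = adjusted p < 0.1 AND
|log₂ FC| ≥ 1, with the fold change computed on raw group means,
second-listed group over first; the orientation is always emitted because
"FC > 1" alone is ambiguous. Both the two-sided (default) and one-sided
fold-change gates are available, and the threshold pair (0.1, |log₂FC|≥1)
is configuration.

*ANOVA + Tukey*: one-way ANOVA per feature with BH adjustment across
features, then Tukey HSD to attribute the effect to a pair; a feature is
significant when both the adjusted ANOVA p and the smallest
Tukey-adjusted pairwise p fall below α = 0.1. Without the across-features
adjustment a null covariate would flag ~10% of features by construction,
which is not how the multi-group results behave. With two groups Tukey's
studentized range collapses exactly to the pooled t-test (tested).

*PLS-DA*: PLS regression (NIPALS deflation, via scikit-learn) of the
centred 0/1 class indicator on the scaled matrix; five components by
default. R²Y is the cumulative explained class variance (the NIPALS score
vectors are orthogonal, so it decomposes per component and is monotone);
Q²Y = 1 − PRESS/TSS from seeded stratified 10-fold cross-validation (the
fold count shrinks to the minority class size when needed); VIP follows
the standard formula, which forces mean(VIP²) = 1 exactly — an identity
the tests assert to 1e-8.

*Random forest*: an explicit bagging loop over CART trees
(scikit-learn's `DecisionTreeClassifier`) with bootstrap samples of size
n and mtry = round(√p) candidate features per split (2656 features → 52),
500 trees by default with a hard cap of 1000. The explicit loop exists
because both quality metrics are out-of-bag: the OOB error is the
misclassification rate of majority OOB votes, and the mean decrease in
accuracy of feature j is the average over trees of the drop in that
tree's OOB accuracy when column j is permuted — the importances the
0.00016 consensus threshold refers to. All randomness is seeded; OOB
quantities are therefore exactly reproducible for a seed, and only
stable in regime across seeds.

*Consensus*: the three significant sets (volcano; VIP > 1.5;
MDA > 0.00016) are partitioned into the 7 Venn regions; the triple
intersection, ranked by adjusted p, is the robust marker list.

## The synthetic cohort

The generator reproduces the study *design*: 101 subjects (phenotype
category frequencies matching the cohort table: 50/101 female, 16/50
contraceptive users, 53/28/20 alcohol, 92/101 coffee, ...), three breath
replicates per subject, each extract acquired in 2 modes × 2 mass-range
methods, pooled-QC injections at the start, after every 12 analytical
samples, and at the end of each sequence.

Per metabolite and acquisition the expected intensity is

  10^base · Π effects(profile) · dilution(extract) · batch · mode-efficiency,

with log-normal scatter (σ = 0.15 log₁₀ per acquisition), a per-extract
dilution factor (σ = 0.2 log₁₀ — the variable droplet yield that PQN must
remove; stored in the truth manifest), per-batch factors (σ = 0.15
log₁₀; global shifts only, which is all that QC-anchored global
normalization can correct), dropout below the detection limit of 10⁶
counts, a small sporadic detection-failure probability (≤ 2% — random
whole-acquisition loss of an intense peak is rare on a real instrument;
near-LOD dropout emerges from the noise model instead), and m/z jitter of
0.3 ppm (so a 1 ppm gate keeps ≈ 99.9% of true matches). The three most
abundant isotopologues are emitted per ion. Base intensities are drawn
from 10^6.8–10^8.5 counts. QC injections are the deterministic pooled
mean of all extracts' expected spectra with 0.05 log₁₀ injection noise,
so QCs are tighter than analytical samples by construction — as they
must be for PQN anchoring to make sense.

Planted effects multiply the affected subgroup (females; contraceptive
users; alcohol abstainers — the orientation in which such effects were
reported) by a fold drawn from the requested range, half of them
inverted so both orientations occur. The manifest records every marker
and fold, every dilution and batch factor: the recovery experiments in
the tests and the acceptance script compare against it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: isobaric overlap in the reference list (the
bundled synthetic list enforces ≥ 5 ppm separation between all candidate
ions, so annotation is unambiguous by construction; a real database would
produce ties resolved only putatively), electronic noise peaks and
contaminants, within-run instrument drift, correlated metabolite panels
(all metabolites are independent given the per-extract factors), profile
peak shapes, and saliva-contamination structure. Recovery rates measured
here are therefore upper bounds on what identical settings would achieve
on instrument data.

## Problem sizes and determinism

The analysis scripts and the acceptance script run the full-size design
(101 subjects, 1212 analytical + 108 QC acquisitions) with a
220-metabolite panel — large enough that every stage (mode merge, method
dedup, QC anchoring, consensus) is exercised with realistic sparsity,
small enough to run in minutes on one CPU. The test suite uses a
40-subject cohort for recovery properties and 20-subject cohorts for the
10-seed null calibration. Every stochastic component (generator,
cross-validation folds, forest bootstraps and permutations) takes an
explicit seed; reruns with the same configuration are byte-identical.

## Known limitations

- The fine-structure score is an analogue of an unpublished vendor
  metric; the 300 cut-off is transferred by convention, not calibration.
- Whether the prevalence fractions refer to subjects or acquisitions is
  a design choice here (subjects, post-consensus); the acquisition-level
  variant is available via configuration.
- Mode merging assumes one row per formula per mode table (guaranteed
  after per-mode deduplication, which the pipeline applies first).
- The MDA threshold 0.00016 is applied to raw mean-decrease-in-accuracy
  values; other software may scale importances differently.
- No retention time and no MS/MS: identities are formula-level and
  putative by nature of direct infusion.
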