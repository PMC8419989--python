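# Methods

`lesionrad` reimplements a complete lesion-radiomics diagnosis chain for
differentiating multiple sclerosis (MS) from neuromyelitis optica (NMO) on
brain MRI: radiomic feature extraction from dual-sequence (T2 + T1-MPRAGE)
lesion volumes of interest, multi-level feature selection, a balanced
random-forest classifier, exact Shapley interpretation, and the clinical
summary statistics that accompany such a study. Because patient MRI cohorts
of this kind are not publicly deposited, the package ships a synthetic-cohort
generator that reproduces the study *design* — two diagnostic classes, two
scanner field strengths, dual sequences, realistic clinical covariates — so
every stage is testable end to end.

## Feature extraction

Each sequence yields **1118 named features**: an 86-feature panel computed on
the original image, on 4 Laplacian-of-Gaussian (LoG) filtered images, and on
8 single-level wavelet subbands (86 × 13 = 1118). The 86-panel decomposes as
18 first-order + 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM; these family sizes
are the standard panels of the radiomics literature and reproduce the usual
taxonomy subtotals (18 intensity, 68 texture, 344 LoG, 688 wavelet features
per sequence). Names render as `H-<seq>-<filter>-<family>-<stat>` and integer
ids come from a deterministic enumeration (sequence → filter → family →
stat); ids are stable for a configuration but are not meaningful beyond
ordering.

Key numerical conventions (all config-exposed via `ExtractionConfig`):

- **Discretisation** — fixed bin width (default 25 intensity units),
  minimum-referenced: `level = floor((v − min)/w) + 1`. This makes every
  discretised feature invariant to adding a constant to the intensities.
- **GLCM** — distance 1, the 13 unique 3-D directions, symmetric matrices,
  feature values averaged over directions with at least one valid voxel
  pair; directions without pairs are skipped. A single-level VOI degenerates
  to a one-cell matrix (joint entropy 0, Idn = Idmn = 1); `Correlation` is
  defined as 1 there.
- **GLRLM** — runs along the same 13 directions, feature values averaged.
- **GLSZM** — 26-connected zones (`scipy.ndimage.label` with a full
  3×3×3 structuring element).
- **GLDM** — 26-neighbourhood at Chebyshev distance 1, dependence threshold
  α = 0 (neighbour counts as dependent only when its level is equal). The
  dependence index is 1 + (number of dependent neighbours) so isolated
  voxels occupy column 1 and no feature divides by zero.
- **Undefined features** (empty matrices, zero-variance denominators) are
  imputed as 0 so downstream selection never sees missing values.
- **LoG filter** — the scale-normalised analytic kernel `σ²∇²G_σ` sampled at
  voxel-centre offsets in physical (mm) coordinates, truncated at 4σ, applied
  separably with nearest-edge padding. The second-derivative taps are
  DC-corrected to sum exactly to zero, so constants (and interior ramps) map
  exactly to zero despite truncation. Default scales σ ∈ {2, 3, 4, 5} mm,
  matching the `log2 … log5` name family.
- **Wavelet subbands** — single-level, undecimated, separable decomposition
  with periodic boundary; subband letter *i* is the filter applied along
  array axis *i*. Each 1-D filter is the orthonormal decomposition filter
  (Haar by default, any PyWavelets kernel accepted) scaled by 1/√2, which
  restores the Parseval identity the decimated transform would have: total
  energy over the 8 subbands equals input energy. Keeping subbands on the
  input grid means the lesion mask applies unchanged.
- **Standardisation** — per-column z-scoring against a reference table
  (training set statistics for test data); zero-SD columns map to 0 and are
  recorded in `reference_stats`.

## Synthetic cohorts

The generator's defaults encode the emulated study: cohort cells
(MS, 3T) = 38, (NMO, 3T) = 30, (MS, 1.5T) = 40, (NMO, 1.5T) = 8 (116
subjects, 78 MS / 38 NMO); age Normal(36.5, 10.0) for MS and
Normal(40.9, 11.7) for NMO; EDSS Normal(2.9, 1.5) / Normal(3.8, 1.6)
truncated to [0, 10] and rounded to the half-point grid; sex Bernoulli with
male rates 27/78 and 7/38; disease duration log-normal moment-matched to
56.8 ± 54.1 and 66.4 ± 58.4 months. Only the first two moments of these
covariates are published; the distribution families are our choice.

*Table mode* (the default test path) draws standard-normal radiomic features
(optionally block-equicorrelated), then plants a ±d/2 class-mean offset on
the first `n_discriminative` registry names (alternating T2/MPR) and an
additive `shift_size`-SD scanner offset on the next `n_scanner_shifted`
names. The batch effect is a location shift because that is what a rank-sum
robustness filter can detect; a scale-only variant would require a different
test. `clinical_effect_size` optionally replaces the EDSS group means with a
symmetric standardised separation for planted-recovery experiments.

*Image mode* grows 1–3 random ellipsoidal lesions (3–6 mm radius by default;
lesion count/size distributions are not published, so these are arbitrary
and config-exposed) inside an ellipsoidal brain-like envelope on a shared
grid (volumes are generated pre-aligned; registration is out of scope).
Class is encoded as the spatial autocorrelation length of the within-lesion
texture (MS 0.6 voxels, NMO 1.6), scanner as a global intensity gain (0.8 at
1.5 T) plus a noise-SD change. This emulates just enough structure for the
extraction + screening chain to find a planted texture difference; it is not
an MRI physics simulation — no partial-volume effects, bias fields,
anatomy, or registration error — so passing tests demonstrate pipeline
correctness, not clinical performance.

Identical `SynthConfig` (including seed) reproduces cohorts bit-exactly.

## Multi-level feature selection

Univariate level (two-sided Wilcoxon rank-sum, α = 0.05, no multiplicity
correction):

1. **Scanner-robustness filter** — keep a feature only if its 1.5 T vs 3 T
   comparison is *not* significant (p ≥ α). The comparison runs within each
   diagnostic class and a feature is removed if either stratum comparison is
   significant; pooling classes would confound the class imbalance across
   scanners (38/30 vs 40/8). A pooled variant is available
   (`within_class=False`).
2. **Class-relevance filter** — keep a feature only if its MS vs NMO
   comparison is significant (p < α).

The rank-sum test uses exact enumeration when the pooled sample has ≤ 12
observations and no ties, and the tie- and continuity-corrected normal
approximation otherwise; when every pooled value is identical the variance
degenerates and p is defined as 1. Univariate AUC uses the Mann–Whitney
identity with ties counted ½ and is reported orientation-folded,
max(AUC, 1 − AUC).

Multivariate level (the pyramid): random-forest sequential forward selection
(RF-SFS) runs separately within T2, MPR and clinical candidates (caps of 10
per modality), then once more over the union of the three preliminary
phenotypes (fusion cap 8, matching the 3 + 4 + 1 panel size of the emulated
study). The four clinical covariates enter their SFS directly rather than
through the radiomic filters: they are scanner-independent by construction,
and EDSS belongs in the comparison panel regardless of its univariate
p-value. Each SFS step adds the candidate maximising the stratified 5-fold
cross-validated AUC of a balanced random forest on the current set +
candidate; ties break toward the earlier candidate (lower feature id). The
internal scorer uses a 50-tree forest — the score only ranks candidate
subsets, and at these sample sizes a larger internal forest changes cost,
not ranking behaviour (`sfs_trees` raises it). Selection stops at the cap or
after 3 consecutive steps without improving the running maximum
(`patience`), and the returned phenotype is the prefix achieving the global
trace maximum. Everything is deterministic given the seed.

**A caveat that matters for interpretation:** the internal CV AUC trace is a
*selection criterion*, not a performance estimate. Because each step
maximises a noisy score over many candidates, the trace maximum is
optimistically biased — on pure-noise inputs at n = 120 with ~17
filter-surviving candidates it concentrates around 0.74–0.79, not 0.5.
Honest performance numbers come from the model module's cross-validation on
a fixed phenotype and from bootstrap evaluation on a held-out test set; the
shipped pipeline selects on the training split only.

## Diagnostic model

`MMRFModel(table, phenotype).fit()` trains the balanced random forest and
returns `MMRFResults` with the trained bundle, a 10-fold CV report and
`summary()`. Class imbalance is neutralised two ways, per tree: every class
is first undersampled *without* replacement to the minority count and then
bootstrapped within class (this keeps the number of distinct subjects per
class symmetric — a plain with-replacement balanced draw leaves the majority
class with more distinct points per tree and measurably biases pure leaves
toward it), and split criteria use inverse-class-frequency weights (uniform
under the balanced bootstrap, kept for generality). Defaults: 500 trees,
unlimited depth, √p features per split. The positive class is NMO — the only
orientation consistent with the emulated study's reviewer confusion matrix —
and is switchable.

Evaluation: stratified 10-fold CV (per-fold metrics at threshold 0.5,
averaged; sample SD, ddof = 1) and 1000-resample bootstrap of the test set
(stratified within class by default; a plain-resampling variant redraws
resamples that lose a class). Reports carry mean ± SD, 95% CI (percentile
for bootstrap, normal-approximation for CV folds) and the stability
statistic `AUC_RSD = AUC_STD / AUC_MEAN`, which holds exactly in every
report by construction. For a hard (binary) predictor the rank AUC equals
balanced accuracy, (sensitivity + specificity)/2 — asserted as a test
identity.

## Interpretation

Shapley values are computed exactly: the interventional (marginal) value
function v(S) is the mean positive-class probability after fixing the
features in S to the explained subject's values and drawing the rest from
the background table (the full training table by default), enumerated over
all 2^M coalitions (M ≤ 16; the intended phenotypes have M ≤ 8). This gives
machine-precision local accuracy (base value + Σφ = prediction) and the
dummy/symmetry/additivity axioms by construction, and avoids tree-path
approximations. Percentage contributions use |φ| normalisation — the only
convention that yields positive percentages for mixed-sign contributions.
Model-level importance is the mean |φ| per feature across subjects;
value-vs-contribution trends are OLS slopes of φ against the feature value,
with the sign reported. Waterfall/beeswarm/dependence plots are provided.

## Clinical statistics

Group comparisons from printed summaries use the Welch unequal-variance t
(recomputing the emulated study's EDSS row from its printed summaries gives
p = 0.005 under Welch but 0.004 under pooled Student; both variants are
implemented, Welch is the default) and the Yates continuity-corrected χ² for
2×2 tables (which reproduces the printed sex p = 0.114; the uncorrected
statistic gives ≈ 0.072). Reviewer-style confusion matrices are summarised
as accuracy/sensitivity/specificity/hard-AUC, and `infer_class_totals`
reconstructs the class split behind printed misdiagnosis counts by
exhaustive integer search over both positive-class orientations, flagging
ambiguity. Feature–clinical correlations default to Pearson with
t-distribution p-values (Spearman available; the underlying study names
neither), with sex 0/1-coded.

## Problem sizes in the shipped tests

The planted-recovery experiment uses 504 radiomic features (252 per
sequence, 4 informative at d = 1.2, 4 scanner-shifted) + EDSS at d = 1.2
over 120 subjects and 10 selection seeds, with two all-noise control seeds;
oracle equivalence uses 100 random VOIs of at most 4×4×2 voxels; Shapley
sampling agreement uses 10⁴ permutations of an 8-feature model against the
exhaustive values. These sizes were chosen so the whole suite exercises
every stage at full fidelity while remaining comfortable to run on a
laptop.

## Known limitations

- The generator emulates the study design, not MRI physics; image-mode
  class/scanner effects are stylised.
- Feature ids printed by other implementations arise from their own
  enumeration orders and are not expected to match ours.
- No multiple-testing correction in the univariate filters (by design, as in
  the emulated analysis).
- Shape features, 2-D extraction, resampling harmonisation and gray-level
  normalisation beyond binning are out of scope.
- The SFS trace is selection-biased under the null (see above); treat it as
  a search record, never as a performance claim.
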