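# Methods

`pcnradiomics` re-implements, as a tested pipeline, a CECT-radiomics workflow
for preoperative discrimination of three pancreatic cystic neoplasm subtypes
— serous cystadenoma (SCA), mucinous cystic neoplasm (MCN) and intraductal
papillary mucinous neoplasm (IPMN). This note records the models, the
numerical conventions, and the design choices made where the design was
genuinely open.

## Image preprocessing and quantization

A case is a 3D CT volume in Hounsfield units with a co-registered binary
tumor mask. Before any quantification the case is resampled to a normalized
1 × 1 × 5 mm voxel grid (linear interpolation for intensities, nearest
neighbour for the mask, via `scipy.ndimage.zoom`), and the ROI intensities
are quantized to N_g = 64 gray levels with equal-width bins spanning the
ROI's own min–max range:

    level(v) = min(N_g, 1 + floor(N_g · (v − v_min)/(v_max − v_min)))

A constant ROI maps to level 1 throughout (a defined degenerate branch, not
an error). Min–max quantization makes every downstream feature invariant to
affine intensity rescaling, which is the purpose of the normalization: it
removes scanner- and protocol-dependent intensity scale.

## Feature families

Per quantized image the package computes 47 features: histogram (7: mean,
variance, skewness, kurtosis, energy, entropy, uniformity — all moments of
the discrete level distribution p(i), entropy in bits, energy the normalized
second raw moment of levels, distinct from uniformity Σp²), GLCM (9), GLRLM
(13), GLSZM (13) and NGTDM (5, classic coarseness/contrast/busyness/
complexity/strength with ROI-restricted 26-neighborhoods). The same 47 are
computed on each of the 8 subbands of a single-level 3D stationary wavelet
transform (orthogonal 8-tap Daubechies-4; the undecimated transform keeps
subbands on the input grid so the mask applies unchanged; with the
normalized transform total subband energy equals input energy). Subbands are
re-quantized to 64 levels independently because their value ranges are not
HU. The default registry is therefore 9 × 47 = 423 named features,
`<Subband_>Family_Feature`.

Conventions chosen where several exist in the literature:

* GLCM and GLRLM merge (sum) the 13 unique 3D directions into one matrix
  before normalization; GLCM counts both orderings of each voxel pair.
* GLRLM run percentage is N_runs/(N_voxels · N_directions) so it stays in
  (0, 1] for merged matrices; a single-direction matrix is available via the
  `directions` argument, for which RP = N_runs/N_voxels.
* GLSZM zones are 26-connected components of equal level.
* Zero-variance ROIs have skewness = kurtosis = 0 by convention; GLCM
  correlation of a single-level ROI is 1; the NGTDM coarseness denominator
  is floored at 1e-12 (so a flat ROI reports the capped maximum 1e12).
  These keep degenerate phantom cases finite.

## Segmentation-uncertainty robustness

Manual delineation uncertainty is mimicked by perturbing each axial slice of
the mask independently: an action drawn uniformly from
{expand, erode, keep}, and for expand/erode a disk radius drawn uniformly
from 1–4 pixels; morphology is strictly in-plane, and a slice fully erased
by erosion keeps its centroid voxel so masks never become empty. Two
perturbed variants plus the original give three segmentation sets per case.
Random draws are keyed by (seed, case, variant, slice) so a slice's
perturbation does not depend on evaluation order.

Per-feature robustness is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — across patients × 3 segmentations, computed
from the ANOVA mean squares; features with ICC > 0.75 are kept. ICC(2,1) is
used because the segmentation sets act as raters and absolute agreement is
what robustness means.

## Feature screening

Stages only remove features, so survivor sets are nested:

1. ICC > 0.75 (all patients — segmentation agreement does not depend on the
   split);
2. greedy Pearson pruning on the training cohort until all surviving pairs
   have |r| ≤ 0.75 (drop the member of the worst pair with the larger mean
   absolute correlation; lexicographic tie-break; constant features count as
   uncorrelated);
3. Kruskal–Wallis across the three subtypes at α = 0.05 for radiomics
   features and continuous clinical factors; chi-squared / continuity-
   corrected chi-squared / Fisher for categorical clinical factors, the test
   chosen by the expected-count rule (plain χ² if all expected ≥ 5; Fisher
   if any expected < 1 or a 2×2 with an expected < 5 and n < 40; corrected
   χ² for remaining 2×2). Fisher p-values for tables larger than 2×2 are
   seeded Monte Carlo estimates over tables with the observed margins.
4. Boruta-style all-relevant selection on the significant radiomics features
   joined with the significant clinical factors (categoricals
   integer-coded), α = 0.01, up to 100 iterations.

The shadow-feature selector fits a random forest each iteration on the full
design [all originals | fresh independent shuffles of all originals] and
scores a hit for each undecided feature whose importance exceeds the best
shadow importance. Importance is out-of-bag permutation importance as a
Z-score (mean per-tree OOB accuracy drop / its standard error — the classic
random-forest scaling). Hits are tested against Binomial(iterations, ½)
two-sidedly with Bonferroni correction over the feature count. The full
shadow ensemble is kept for the whole run: in a variant where rejected
features' shadows left the design, survivors late in the run raced only a
handful of shadows, and noise features with spurious sample correlation were
confirmed in most null runs. With the full ensemble, null designs (50 noise
features, n = 90) confirm nothing across all tested seeds while planted
signals at standardized separation ≳ 1.9 are recovered completely.

## Classifiers

The cohort is split 70/30 by per-class seeded permutation with training
count = nearest integer to 0.7 × class size (76/40/48 → 53/28/34). Three
families are tuned by stratified 4-fold cross-validation:

* **SVM** — kernels linear, laplacian (exp(−σ‖x−y‖₂)), gaussian
  (exp(−σ‖x−y‖²)), ANOVA-RBF ((Σᵢ exp(−σ(xᵢ−yᵢ)²))^d, d = 1 default);
  C ∈ {1..10}; σ by the median heuristic on training distances; one-vs-one
  pairwise voting with decision-value tie-break (precomputed-Gram
  `sklearn.svm.SVC`); selected by mean CV misclassification.
* **Random forest** — bagged trees with `mtry` candidate features per split;
  selected by OOB error; the OOB misclassification trajectory is recorded
  after every tree (cumulative vote, ties to the lowest-indexed class). The
  default grid uses 500/1000 trees with mtry ∈ {1, 2, 3}; the tree count is
  a scaled-down search space chosen because the tested behaviour is OOB
  stabilization, which these phantoms reach well before 1000 trees.
* **ANN** — one sigmoid hidden layer (10–15 units), softmax output,
  cross-entropy + decay·Σw² over all parameters (decay ∈ 2…0.0625), L-BFGS
  from seeded uniform(−0.7, 0.7) restarts (5 by default, 2 inside CV), best
  training loss kept; selected by mean CV accuracy. If no restart reports
  convergence the best-effort model is returned with a `converged=False`
  flag and a warning rather than an exception, so a routine L-BFGS
  iteration-cap stop cannot abort a grid search.

Features are z-scored on training statistics for SVM and ANN and used raw
for the forest. Grid ties resolve to the first entry of a deterministically
ordered grid (smallest C; fewest units then smallest decay; fewest trees).
All randomness flows from one seed through named counter-based substreams.

Evaluation: 3×3 confusion matrices (rows predicted, columns true, order
IPMN/MCN/SCA), per-class precision = TP/row sum, recall = TP/column sum,
F1 = 2PR/(P+R) (0 when P + R = 0, flagged), overall accuracy = trace/total.
Display rounding is half-up at 4 decimals; internal values are unrounded.

## The synthetic cohort

No patient images are distributed with the workflow, so a phantom module
generates cohorts with the statistical structure the analysis assumes. A
tumor is an axis-aligned ellipsoid (radii jittered ±20%) on a 40 × 40 × 60 mm
grid at 1 × 1 × 5 mm spacing, filled with a stationary Gaussian random field
(white noise smoothed with an isotropic Gaussian kernel of width equal to
the class's correlation length) that is rank-transformed through a skewed
quantile map and snapped to a class-specific number of effective intensity
levels. The quantile map is skew-normal for |skew| ≤ 0.9 and a mirrored
lognormal (log-scale solved from the lognormal skewness identity) beyond
the skew-normal's attainable range. Texture scale and histogram shape are
therefore controlled independently — the two feature families the screening
is expected to recover.

Per-case biological variability jitters the generative parameters (skewness
±0.25, mean ±4 HU, sd/correlation length/level count ±15%): patients within
a class are not parameter-identical, and this between-patient variance is
exactly what the ICC numerator measures. The background is spatially white
noise pushed through the same marginal distribution as the lesion — the
isointense-margin situation in which manual delineation is genuinely
uncertain. Boundary perturbations consequently change spatial texture but
not histogram shape, mirroring the empirical finding that first-order
features survive segmentation jitter while many texture features do not.
Masks still matter: the field inside the ROI is spatially correlated, the
background is not.

Default class parameters (the package's study conditions, chosen once):
SCA fine-textured (3 mm), right-skewed (+1.1), 10 effective levels,
30 ± 12 HU; MCN intermediate (6 mm, +0.3, 24 levels, 45 ± 14 HU); IPMN
coarse (10 mm), left-skewed (−0.8), 48 levels, 60 ± 16 HU. Clinical
covariates: CA 19-9 and CEA log-normal with class-dependent medians
(8/20/60 U/mL and 1.5/2.5/4.5 ng/mL), age truncated-normal (52/45/66 y,
bounds 18–90), sex Bernoulli (female probability 0.70/0.95/0.30); the
remaining fields of the covariate table (location, diameter, liver enzymes,
platelets, albumin, AFP, ferritin, seven binary history flags, blood type)
are drawn identically across classes so the screen must reject them. The
published covariate table pools classes, so the class-conditional parameters
are free defaults, not calibrated values.

What the phantoms do **not** emulate: pancreatic anatomy, contrast kinetics,
CT physics (beam hardening, artifacts, noise texture), inter-rater
segmentation behaviour beyond expand/erode/keep, and correlations between
clinical covariates. Passing tests therefore demonstrate that the pipeline
recovers planted statistical structure under the stated assumptions — not
clinical performance on real patients.

## Problem sizes in the test suite and acceptance script

The end-to-end study runs at 30 cases per class (reduced from the emulated
76/40/48 composition); the ICC-retention study uses 20 replicates of 12
cases; the selector's plant-and-recover study uses 20 seeds at n = 90 with
5 planted and 45 noise features. These sizes were chosen so the full suite
exercises every stage at meaningful power while remaining convenient to run
end-to-end; the generator makes larger cohorts a one-argument change.

## Known limitations

* The feature registry totals 423 features; extending it (e.g. additional
  GLCM statistics) is a config-registry change but no attempt is made to
  match any particular larger catalogue.
* The r×c Fisher p-value is Monte Carlo, not exact.
* The ANN is a dense single-hidden-layer network; no early stopping beyond
  the L-BFGS iteration cap.
* OOB bookkeeping reconstructs per-tree bags from scikit-learn's stored
  tree seeds (`_forest_utils`), which relies on a private but
  version-checked scikit-learn helper.
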