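# Methods

## Density-similarity connectome

Each ROI's uptake sample (≥ 10 values, ≥ 2 distinct) is smoothed with a
Gaussian kernel density estimate on a uniform grid of 2⁹ = 512 points
(configurable; any power of two ≥ 64).  Bandwidth selection is automatic:
Silverman's rule by default, with Scott's rule and the improved
Sheather–Jones diffusion plug-in (solved by fixed point on a DCT mesh, with
Silverman fallback on non-convergence) as alternatives.  The method used is
recorded in the matrix metadata, because the bandwidth visibly affects edge
values at small voxel counts.

For a pair of ROIs the two densities are evaluated on a **shared** uniform
grid spanning the union of the two sample ranges extended by three
bandwidths on each side.  Densities are floored at ε = 1e−12 (configurable)
and renormalised, which keeps the divergence finite when supports barely
overlap; the floor's contribution is negligible whenever the densities
genuinely overlap.  Grid masses pᵢ ∝ density × spacing are renormalised to
sum to one and the edge weight is

    D = Σᵢ (pᵢ − qᵢ) ln(pᵢ/qᵢ)   (≡ Σ pᵢ ln(pᵢ/qᵢ) + qᵢ ln(qᵢ/pᵢ)),
    KLS = exp(−D).

Natural logarithms throughout, so D is in nats.  The diagonal is set to
exactly 1 rather than recomputed.  Whether the original analyses used a
global or per-pair grid is not determinable from their description; the
per-pair grid was chosen because it keeps resolution adaptive to each pair's
support, and the choice is recorded in metadata.  There is no randomness in
this stage: identical inputs give bit-identical matrices.

## Nodal inference

Nodal strength is the off-diagonal row sum.  Group comparison is per-ROI
OLS of strength on a 0/1 group indicator (control = 0, so positive t means
higher strength in cases) plus age and sex; two-sided p on the group
coefficient; Benjamini–Hochberg q across ROIs.  OLS with covariates is the
minimal model consistent with "age and sex as covariates"; the design is
checked for full rank so that perfectly confounded covariates fail loudly
rather than silently.

## Expression preprocessing

* **Intensity filter** — a probe is dropped only when its intensity is
  below 1.5 × background in *all* of its samples (strict inequality, so a
  probe exactly at threshold survives).
* **Differential stability** — for each probe, the mean over donor pairs of
  the Spearman correlation of its regional profile (pairs sharing ≥ 2
  regions); the max-DS probe represents the gene, exact ties breaking to
  the lexicographically smallest probe id.  Genes with no measurable probe
  are dropped with a warning.
* **Scaled robust sigmoid** — per gene,
  s = 1/(1 + exp(−(x − median)/(IQR/1.35))), then min–max rescaled to
  [0, 1].  The 1.35 makes IQR/1.35 a normal-consistent scale estimate.  SRS
  is applied once per donor profile before donor averaging; it is *not*
  idempotent, so the builder records `srs_applied` in the matrix metadata
  and the pipeline never re-applies it.

## PLS inference

Predictors (gene columns) and the response (t-map) are z-scored.  The first
component is extracted with scikit-learn's NIPALS PLS; for a single
response the component-1 weight vector is analytically the normalised
covariance X'y, and the permutation/bootstrap engines use that closed form
(a test asserts it matches the NIPALS component).  The component sign is
fixed so the score–response correlation is non-negative; "weights" are the
X-weights, with X-loadings also exposed since the two are often conflated.

* **Permutation test** — the response is permuted over regions (default
  5000 times), the component refitted, and
  p = (1 + #{r\* ≥ r}) / (n_perm + 1), so p ≥ 1/(n_perm+1) and the null is
  conservative at the add-one level.
* **Bootstrap z** — regions are resampled with replacement (default 1000),
  each replicate sign-aligned to the original weights by inner product, and
  z = original weight / bootstrap SD.  Replicates are compared on the
  covariance scale (X'y without per-replicate unit-norm rescaling): with
  thousands of null genes the norm of X'y grows systematically under
  resampling, and dividing by it would shrink all replicates in common and
  inflate null |z| about 30%.  On the covariance scale the null z SD is
  ≈ 1.0 and the z > 3 / z < −3 gene sets admit ≈ 0.4% of null genes.  Gene
  *ranking* is unaffected (the two scales differ by one constant).
* Gene–map correlations are plain Pearson with two-sided p; nothing is
  partialled out.

## Covariance networks

Animals × regions SUV tables are z-scored per region (which leaves Pearson
r unchanged but makes the z-scoring convention explicit) and correlated.  The
random-shift null independently permutes each region's values across
animals, destroying covariance while preserving marginals.  Positive and
negative observed correlations are assessed against their own null tail,
with add-one correction, and the tail p is doubled (capped at 1) to give a
two-sided edge p — without the doubling, ~10% of null edges pass p < 0.05
because the tail is chosen after seeing the sign.  The raw one-sided tail
matrices are kept alongside.  Thresholded networks zero entries with
p ≥ α (α ∈ {0.05, 0.01} by default).

Signed weighted clustering follows the Zhang–Horvath form generalised to
signed weights: weights rescaled by the maximum magnitude, and

    Cᵢ = Σ_{j≠k} wᵢⱼ wᵢₖ wⱼₖ / Σ_{j≠k} |wᵢⱼ wᵢₖ|  ∈ [−1, 1],

which is 1 on complete positive unit graphs and reduces to the ordinary
weighted clustering when no edge is negative.  Hubs are nodes at or above
the 75th percentile (midpoint interpolation, ties included) of total
|strength| or degree.  "Negative strength" is reported as the magnitude
Σ|negative weights|, and comparisons use that convention.  The
between-group edge test permutes group labels (canonical pooled row order,
so swapping the group arguments reproduces the identical null) on the plain
correlation difference; a Fisher-z variant is available.  Per-edge p-values
are uncorrected by default, with optional BH output downstream.

## Synthetic cohorts

The generators define the data-generating conditions every test runs under.

* **Human cohort** — per-cohort ROI baseline means μᵣ ~ N(1.5, 0.15) on an
  SUVR-like scale; voxel values N(μᵣ, noise_sd) with noise_sd = 0.15 by
  default (a log-normal option exists for skewed uptake).  Within-ROI
  voxel spread comparable to the between-ROI mean spread is the realistic
  regime for smoothed PET, and it is also the regime in which a planted
  deficit propagates coherently into the similarity profile: when regional
  means are far apart relative to voxel spread, pairwise KLS changes under
  a location shift cancel in sign and the planted effect becomes invisible.
  Cases receive `effect_shift × noise_sd` in the chosen ROIs.  Age is
  uniform on [18, 60], sex Bernoulli(1/2), independent of group unless the
  `age_confound` knob (years added to case ages) is set to exercise
  covariate adjustment.  One global seed expands through SeedSequence
  substreams, one per subject, so enlarging a cohort never perturbs
  existing subjects.
* **Gene matrix** — planted genes are r·z(target) + √(1−r²)·noise on a
  log2-microarray-like scale (baseline 7, unit spread); the rest are pure
  noise.  With multiple donors and probes per gene, a long probe table is
  emitted with per-donor offsets (SD 0.3), probe noise increasing with
  probe index (so the first probe is the most stable), and a constant
  background level, giving the probe-collapse and filtering stages
  something real to do.
* **Mouse cohort** — multivariate normal SUV with a block-structured
  correlation matrix (blocks either shared or per group); the implied
  matrix is checked for positive semidefiniteness and sampled through a
  jittered Cholesky factor.

What the generators deliberately do **not** emulate: spatial voxel
autocorrelation, partial-volume effects, scanner noise spectra,
hemispheric asymmetries of donor sampling, or gene–gene co-expression
structure beyond the planted map correlation.  Passing recovery tests
therefore show the statistical machinery is sound under clean planted
structure, not that effect sizes on real PET or microarray data will match.

## Problem sizes and numerical choices

Simulation suites run at reduced scale, chosen as the smallest sizes at
which the planted structure is comfortably identifiable: deficit recovery
uses 30 ROIs (6 planted), 150 voxels/ROI, a 256-point grid and 20 subjects
per group over 50 seeds; gene recovery uses 246 regions × 2000 genes over
20 seeds; calibration suites use 200 null datasets (or 50 seeds for edge
nulls) at reduced permutation counts.  Structural checks still run at the
full 246-region / 512-point and 12 × 22 scales.

Known limitations:

* A planted ROI whose baseline mean is isolated from every other region has
  near-zero similarity everywhere, and a further deficit barely moves its
  profile — such ROIs can escape both detection and top-|t| ranking (the
  average top-k overlap of planted ROIs is ≈ 0.78 at the reduced scale,
  against a 0.2 chance level).
* Bootstrap z calibration degrades below ~50 regions (the demo config
  deliberately shows this); gene-set false-admission guarantees hold at
  atlas scale.
* The edge-level permutation p is granular at 1/(n_perm+1); thresholding at
  α close to that granularity is meaningless.
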