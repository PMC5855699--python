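# Methods

## Design

Each subject serves as her own control: methylation at age 18
(nonpregnant) is paired with methylation during the first or second
half of pregnancy, and each pregnancy window is analyzed against the
baseline separately. The deliverable is a two-step analysis — per-CpG
paired change tests, then resampling-based pathway enrichment — plus
gene-region and spatial-clustering summaries.

## Preprocessing

* **β and M scales.** β = M/(c+M+U) with c = 100 (the array
  convention; the offset only matters on the intensity path, since the
  pipeline itself starts from a β matrix). Differential analysis uses
  M = log2(β/(1−β)): β is a proportion with strong heteroscedasticity
  near its bounds, M is approximately Gaussian. β is clipped to
  [1e−6, 1−1e−6] before the logit; the perturbation is below the
  storage precision of array data and keeps M finite.
* **Filters.** Probes with a documented probe SNP at MAF > 1% and
  probes on chrX/chrY are removed; a probe flagged both ways is counted
  under the SNP rule. Peak correction and background-noise removal are
  intensity-level operations; starting from β they are represented by
  an explicit no-op stage with a logged notice.
* **Quantile normalization** forces every sample onto the row-wise mean
  of the sorted columns; ties get the mean of the tied reference values
  (average ranks), preserving within-sample rank order exactly.
* **Batch correction** is the parametric empirical-Bayes location/scale
  model: per-probe standardization preserving the timepoint design,
  normal prior on batch locations, inverse-gamma on batch scales,
  priors estimated across probes, posterior estimates applied, data
  restored. The implementation agrees with Bioconductor `sva::ComBat`
  to ~1e−5 on shared inputs (tested). Only the parametric variant is
  provided.

## Deconvolution (two stages)

* **Surrogate variables** are the top right singular vectors of the
  row-centered M matrix, computed separately for the nonpregnant, the
  first-half, and the second-half datasets (k = 15 by default; k
  truncates with a warning when a dataset has fewer than 16 samples).
  Each probe is residualized on [1, SVs]; the fitted intercept is kept,
  so probe locations survive. Note an inherent limit: residualization
  removes within-dataset factor *variation*, not the dataset-mean
  factor level, so a latent factor whose average differs between the
  baseline and pregnancy sample sets still shifts the time contrast.
  No protection of the time effect is applied when estimating SVs
  (plain SVD per dataset); with time constant within each dataset it
  cannot be absorbed directly.
* **Cell proportions.** Whole blood is modelled as a mixture of seven
  leukocyte subtypes with cell-type-specific signature β profiles.
  Per sample, min‖S·w − b‖² s.t. w ≥ 0, Σw = 1 over the shared
  signature probes, solved by nonnegative least squares with a heavily
  weighted sum-to-one pseudo-row (weight 1000) followed by exact
  renormalization. Sum-to-one is enforced (the classical reference
  method uses ≤ 1); exact compositions are cleaner as model covariates.
  The proportions enter the paired model as time-varying covariates;
  one cell type is dropped from the design because compositions are
  collinear with the intercept.

## Paired test

Model per CpG: M_ij = β0 + β1·time_ij + γ′cells_ij + e_ij, subjects
i with both timepoints, unstructured within-subject 2×2 error
covariance Σ. Estimation is iterated GLS: given Σ, solve the weighted
normal equations; given β, set Σ to the residual cross-product matrix
divided by n − p + 1 (p the fixed-effect rank); iterate to a relative
Σ change below 1e−8, at most 100 iterations (non-convergence falls
back to the last method-of-moments Σ, flagged). The implementation is
vectorized across probes: the sample-level design is shared, so each
iteration reduces to 2×2 weight updates and a batched p×p solve.

The Wald t-test for β1 uses the between–within degrees of freedom for
within-subject effects, df = n − p + 1. This choice is forced by the
spherical limit: with no covariates the estimator collapses to the
mean paired difference with variance var(d)/n, and only df = n − 1
reproduces the classical paired t-test (verified to 1e−6 in tests);
df = n − p would be conservative by one. Degenerate probes (zero
residual variance or perfectly correlated timepoints) are reported
with estimate 0 and p = 1 rather than dropped, keeping the pathway
denominators (155/77/106/10) intact.

FDR is Benjamini–Hochberg. The family is configurable; the default in
the enrichment step applies BH within each probe family (a pathway, or
one 348-CpG draw), mirroring the per-table structure of the raw-p
analysis, with a genome-wide q-value also written to the results.

## Enrichment

Ten random subsets of 348 CpGs (the total pathway CpG count) are drawn
without replacement from each reference universe, excluding the 348
pathway probes from both universes for a clean null. Per-draw seeds
derive from the master seed by a fixed stride and are recorded, so any
draw can be re-derived (the intergenic-exclusion sensitivity redraw
reuses them). Each pathway/draw pair is a saturated two-group
log-binomial GLM; its exponentiated coefficient equals the ratio of
proportions and its Wald interval equals the Katz interval (both
identities are tested). Zero cells fall back to adding 0.5 to all four
cells of the implied 2×2. Draws are combined three ways — combined RR
= pathway proportion / median subset proportion, median per-draw RR,
and medians of the per-draw CI bounds — because the published summary
convention is not internally consistent between the two pregnancy
halves: the first-half RRs equal the ratio of printed proportions, the
second-half RRs do not (they evidently reflect unrounded medians).
All three are reported; none is forced to match the second half.

Subgroup comparisons (the 20 all-three-timepoints subjects vs the full
windows) use the Pearson chi-square on the 2×2 without continuity
correction. Two caveats are deliberate: the subgroup is nested in the
full group, so the two proportions are not independent, and the
subgroup has less power, so its significant proportion runs lower —
the comparison is reported as a descriptive check, as in the original
design.

## Gene regions and clustering

450K annotation tokens collapse to four groups (TSS200/TSS1500 →
Promoter; Body/1stExon → Body; 5′UTR; 3′UTR); multi-gene probes pool
tokens across genes before canonicalization; a probe with no
annotation is Intergenic. Every probe receives exactly one canonical
combination label. The clustering report lists, for each significant
CpG, every probe within ±1500 bp (inclusive boundary) on the same
chromosome with its distance, significance, and direction concordance,
via a sorted-position sweep (verified against the all-pairs oracle).
Positions are 1-based point coordinates; strand is ignored.

## Synthetic cohort

The generator emulates the study conditions: 245 baseline women, 39
first-half and 35 second-half pregnancy samples with 20 complete
triples; 20,000 background CpGs (a deliberate scale-down of a 450K
array, keeping runtimes in seconds) plus 348 pathway CpGs spread over
the real pathway gene panels and 420 cell-signature probes; seven cell
types; seven batches. Sample β is a cell-proportion-weighted mixture
of per-cell β profiles (bimodal M baseline, signature probes offset by
±3 M in their discriminating cell type, other probes given small cell
offsets of SD 0.3 M that create genuine composition confounding);
batch location/scale shifts, latent-factor contributions (5 factors,
loadings SD 0.4 on a random 30% of probes), subject-level set points
(SD 0.8 M), true pregnancy effects, and noise (SD 0.5 M, batch-scaled)
are added on the M scale and mapped back through the inverse logit
with clipping. Effects are injected on the M scale because the tests
run on M; a CpG with an effect shifts in the same direction in both
windows with mildly different magnitudes. Blood composition follows a
granulocyte-dominated Dirichlet with a mild pregnancy shift toward
neutrophilia.

Probe-filter fractions (SNP 0.37, sex chromosomes 0.04) are set so
~60% of probes survive, matching the filtered array. Effect
probabilities (background 0.21; Th1 0.30, Th2 0.38, Th17 0.34, Treg
0.34 with |Δ| ≈ 0.5 M) were calibrated once against the measured
end-to-end power (~0.80–0.90) so the pipeline's observed significance
rates land near 24% background and 28–36% in the pathways — the
regime the method is meant to operate in.

Samples are randomized across batches. This is a deliberate design
choice: when batch is confounded with timepoint, the batch-correction
step itself distorts the time contrast and inflates the per-CpG false
positive rate several-fold — a known failure mode of empirical-Bayes
batch correction under confounding, reproduced here during
development. The generator therefore emulates a plate-randomized
study; confounded designs remain out of scope.

What the generator does not model: Infinium I/II probe-type chemistry,
intensity-level artifacts (so peak correction stays a no-op),
cross-reactive probes, genetic polymorphism effects beyond the SNP
flag, and age-related drift between 18 and conception. Passing
recovery tests therefore show the pipeline is correct under the
assumed mixture-plus-additive-effects model, not that it is robust to
every artifact of real arrays.

## Numerical choices and problem sizes

Iterated-GLS tolerance 1e−8 (relative Σ change), max 100 iterations;
NNLS sum-to-one weight 1000 with exact renormalization; β clip 1e−6;
degenerate-Σ guard at a relative determinant of 1e−10; batched solves
fall back to pseudo-inverse on singularity. The test suite runs its
simulations at reduced sizes (cohorts of 30–60 subjects,
1,200–6,000 background CpGs, 5 SVs where per-timepoint samples are
few) chosen so each check still exercises the full code path; the
acceptance script runs the generator at its default scale. Empirical
calibration figures quoted above are recomputed by the suite and the
acceptance script, not hard-coded.

## Known limitations

* Per-dataset SVA leaves dataset-mean latent shifts in the time
  contrast (above); with few samples and k = 15 it can also absorb
  most genuine within-dataset variance — the pipeline truncates k and
  warns, but small-n/k choices deserve care.
* The denominator df differs from what SAS GENMOD/MIXED would report
  under some ddfm options; the between–within convention was chosen to
  match the paired-t limit.
* The log-binomial GLM can fail to converge off the boundary; the
  closed-form two-group estimate (identical at the MLE for this
  saturated design) is the fallback.
* Cell-proportion covariates are estimates, not truth;
  errors-in-variables leaves some residual composition confounding in
  the per-CpG tests, as in any reference-based deconvolution.
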