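# Methods

## Setting and assumptions

`tsmr` implements two-sample Mendelian randomization (MR): per-variant
association summaries (beta, SE, allele frequency, p, N) for an exposure
and an outcome estimated in non-overlapping GWAS samples.  Validity rests
on the three instrumental-variable assumptions — instruments are
associated with the exposure, independent of confounders of the
exposure–outcome relationship, and affect the outcome only through the
exposure.  The estimator battery and diagnostics exist precisely because
the third assumption (no horizontal pleiotropy) is untestable per variant.

All effects are treated on the scale the input GWAS reports; for binary
outcomes that is the log-odds scale, and results are also reported as
odds ratios.

## Harmonization

Records are matched by variant identifier; chromosome/position
disagreements between builds are warned about, not fatal.  Outcome records
are re-oriented to the exposure's effect allele by swapping alleles,
negating beta and complementing the effect-allele frequency.  Palindromic
variants (A/T, C/G) are dropped unconditionally by default because strand
cannot be resolved from alleles; an opt-in mode keeps them when both
allele frequencies are outside 0.5 ± 0.08 and concordant.  Non-palindromic
records whose alleles match only after strand complementation are
complemented and aligned; any remaining mismatch is dropped as ambiguous.
The harmonization log assigns every input variant exactly one disposition,
so counts are conserved.

## Instrument selection

Filters run in a fixed order: exposure p < 1e-5 (strict), greedy LD
clumping, outcome-association exclusion (p < 1e-5), static exclusion
list, MAF ≥ 0.01, then F = (β/se)² > 10.  Clumping repeatedly keeps the
remaining variant with the smallest p (ties broken lexicographically by
identifier, for determinism) and discards same-chromosome variants within
±10,000 kb at r² ≥ 0.001.  Order matters only through clumping, which must
see the p-filtered set; the MAF and F filters commute.  The LD matrix is
an input (square or long TSV); the package does not compute LD from
genotype panels, and the provenance of the supplied panel is the user's to
record.  F is the standard single-SNP summary approximation; with a Wald
p-value the p < 1e-5 filter already implies F > 19, so the F floor only
binds when the reported p comes from a different association model.

## Estimators

* **Wald ratio** β̂ⱼ = β_Yⱼ/β_Xⱼ with first-order delta SE se_Yⱼ/|β_Xⱼ|.
  The second-order correction is omitted (the common default).
* **IVW**: weighted least squares of β_Y on β_X through the origin,
  weights 1/se_Y².  Default is the multiplicative random-effects variant:
  SE inflated by max(1, √(Q/(J−1))), so underdispersion never tightens the
  interval.  Normal inference.  One instrument degrades to the Wald ratio.
* **MR-Egger**: WLS with a free intercept after orienting all β_X ≥ 0.
  The intercept estimates the average directional-pleiotropy effect;
  inference on t(J−2) with the residual scale floored at 1.
* **Weighted median**: ratios sorted ascending, estimate interpolated at
  the 50 % point of cumulative midpoint weights (cum − w/2)/Σw.  SE from a
  parametric bootstrap redrawing both β_X and β_Y from their reported
  sampling distributions (default 1000 draws, seed required in pipelines).
* **Mode estimators**: argmax of a normal-kernel density over the ratios,
  bandwidth h = φ·0.9·min(sd, IQR/1.349)·J^(−1/5) (modified Silverman,
  φ = 1 by default), evaluated on a 2048-point grid spanning the ratios
  ±3h.  The weighted variant scales kernels by normalized IVW weight.  If
  all ratios coincide the common value is returned.  Bootstrap SE as for
  the median.

Method minima: Egger/median/mode need J ≥ 3; requesting the full battery
with fewer instruments returns only what is computable.

## Sensitivity diagnostics

Cochran's Q over ratio estimates (chi-square, J−1 df) is algebraically
identical to the weighted RSS of the through-origin fit — the test suite
asserts both routes agree to 1e-10.  The Egger intercept test re-exports
the regression intercept on t(J−2).

**MR-PRESSO** is implemented from its algorithmic description (no Python
reference implementation exists): for each variant, the leave-one-out IVW
slope gives an expected outcome beta; the observed global statistic is the
weighted RSS around those expectations; its p-value is the add-one tail
frequency over parametric replicates that redraw both exposure and outcome
betas (so p ≥ 1/(n_sim+1) by construction).  Per-variant outlier p-values
are the analogous add-one tail of the squared weighted residual,
Bonferroni-multiplied by J; the distortion test compares the raw-minus-
corrected IVW difference against the same difference under 1000 random
pseudo-outlier subsets of the observed outlier count.  A single round of
outlier removal and re-estimation is performed, matching common practice.
Defaults n_sim = 1000 and an explicit seed are the package's choices; the
add-one/Bonferroni combination means n_sim must exceed J/α before any
outlier can be declared at level α.

## Screening rules

A candidate exposure–outcome pair survives when: IVW p < 0.05; at least
one of MR-Egger and weighted median has p < 0.05 (the corroboration rule
used in place of panel-wide multiplicity correction; an optional
Benjamini–Hochberg switch exists but is off by default); IVW, Egger and
weighted median agree in sign with pairwise overlapping 95 % CIs (the
operationalization of "consistent direction and magnitude"); Q and
Egger-intercept p > 0.05; PRESSO finds no outliers or the
outlier-corrected estimate keeps sign and significance; and reverse-
direction MR (identical pipeline, roles swapped) is non-significant.
Batch decisions derive per-exposure seeds from the root seed and the trait
identifier, so results are independent of batch order.

## Mediation

β₁, β₂ and β_all are IVW estimates from separately instrumented legs
(configurable to any estimator).  β₁₂ = β₁β₂ with first-order delta SE
√(β₁²se₂² + β₂²se₁²); β_dir = β_all − β₁₂ is computed by subtraction, so
conservation is exact by construction; the mediated proportion
β₁₂/β_all·100 % is reported signed, with the absolute value alongside.
A mediated effect whose sign opposes the total is flagged as inconsistent
mediation (suppression) rather than silently converted to a magnitude —
but only when the β₁₂ 95 % CI excludes zero; a product indistinguishable
from zero is not evidence of suppression, which keeps the flag stable when
the mediator leg is null.  No Sobel refinement and no multivariable-MR
direct effects are attempted.

## Synthetic studies

The generator works directly in summary space; two-sample MR never
consumes individual-level genotypes, and this keeps replication studies at
interactive runtimes.  Each variant receives a true effect from the causal
chain: exposure-instrument SNPs carry γⱼ ~ N(0, gamma_sd²) on the
exposure; mediator-instrument SNPs carry δⱼ ~ N(0, delta_sd²) directly on
the mediator — a real mediator trait has genetics of its own, and without
this block the mediator GWAS would yield no instruments and step-2 MR
would be impossible.  True per-SNP effects are γⱼ (exposure),
β₁γⱼ + δⱼ (mediator) and (β_dir + β₁β₂)γⱼ + β₂δⱼ + sign·αⱼ (outcome),
where αⱼ ~ N(pleiotropy_mean, pleiotropy_sd²) is horizontal pleiotropy
applied relative to the trait-increasing allele of the SNP's own
instrument trait — planted relative to an arbitrary allele orientation, a
directional mean would cancel under Egger's β_X ≥ 0 orientation and be
undetectable by construction.

Observed betas are drawn around the truth with se = 1/√(2·maf(1−maf)·n),
the standard approximation for a standardized continuous trait; for the
binary outcome this stands in for the log-odds SE with n as effective
sample size.  P-values are Wald.  MAFs are uniform on (0.05, 0.5); a
configurable fraction of variants is palindromic and a fraction of
mediator/outcome records is stored on the swapped allele, exercising
harmonization.  LD is block-diagonal (identity by default).  Planted
outliers displace the observed outcome beta of the strongest observed
exposure instruments by `outlier_shift_se` outcome SEs, guaranteeing they
survive exposure-side selection.

Default sample sizes mirror the scale of the public data this design is
used with — n_exp = 18,340 (microbiome-consortium scale), n_med = 3,757
(single-cohort immune-phenotype scale), n_out = 177,028 (biobank
case-control scale); gamma_sd = 0.08 and delta_sd = 0.15 make roughly half
the instrument block clear p < 1e-5 at those sizes.  The `paper-mediation`
preset plants β₁ = −0.19, β₂ = −0.05, β_dir = 0.147, so the total effect
is ≈ ln 1.17 and the true mediated proportion ≈ 6.1 % — the scale of a
published microbiota→immune-cell→colorectal-cancer pathway.  The
`suppression` preset uses β₂ = −0.05 (not larger) so that mediator
instruments are not themselves excluded as outcome-associated.

### Replication studies and what they show

`replicate()` distinguishes estimator-level from pipeline-level studies.
Calibration of IVW and the Egger intercept analyzes the full instrument
block, so J is fixed by design and the measured type-I error and coverage
are properties of the estimators themselves.  The PRESSO and mediation
studies run instrument selection first, as on real data — with one
deliberate exception: the PRESSO study selects on exposure criteria only,
because a 10-SE-displaced outcome beta has outcome p ≈ 1e-23 and the
outcome-association filter would remove every planted outlier before the
outlier test could see it; the study validates the outlier machinery, not
the filter.

These studies demonstrate internal statistical validity (calibration,
recovery of planted truth, determinism), not external validity: the
generator has no realistic LD beyond blocks, no population structure or
sample overlap, no confounding-induced instrument invalidity beyond the
planted pleiotropy models, and genome scales of tens of SNPs rather than
millions of variants.  Passing them shows the pipeline computes the right
quantities and detects the planted pathologies; it cannot show that any
particular real-data finding is causal.

## Numerical choices and degenerate inputs

Ties in clumping break lexicographically; Monte-Carlo p-values use the
add-one convention; random-effects scales are floored at 1; ratio
estimates with β_X = 0 are a domain error (excluded upstream by the F
filter); a zero total effect makes the mediated proportion undefined and
is an error; bandwidth zero (identical ratios) short-circuits the mode to
the common ratio; all stochastic stages consume seeds split
deterministically from one root seed, and identical configuration plus
seed reproduces byte-identical outputs (hash-checked in the tests).

## Known limitations

Matching is by variant identifier only (no liftover); no proxy-SNP search;
no multivariable MR, Steiger filtering, RAPS or contamination-mixture
estimators; LD must be supplied, not computed; binary-trait SEs use the
effective-sample-size approximation; mediation uncertainty ignores the
covariance between β_all and β₁₂ estimated from overlapping instrument
sets.
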