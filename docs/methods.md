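# Methods

## Setting

A small experimental crop panel: ~18 inbred-ish lines, ~124 plants, ~192
SNPs spread over ~99 assembly scaffolds mapped (mostly) to 9 chromosomes.
Scaffold order along chromosomes is unknown, so all positional reasoning is
within-scaffold. The phenotype is binary (high/low root vigor), constant
within line, and strongly unbalanced (15 high-vigor lines with 100 plants
vs 3 low-vigor lines with 24).

## Genotype QC

Editing runs in a fixed order: (1) remove all but the first member of every
duplicate-sample group, where duplicates are samples agreeing at 100% of
jointly called genotypes (missing cells are ignored; a pair with no joint
call is not a duplicate); (2) remove markers with call rate ≤ 1 −
`max_snp_missing` (default 0.85), recomputed on the surviving samples;
(3) recompute MAF on the surviving samples and remove markers with MAF ≤
`min_maf` (default 0.025). Both filters use "≤" semantics deliberately, so
a marker sitting exactly on a threshold is removed. MAF is computed from
observed allele counts only. The QC report prints the remaining missing
count together with its denominator (samples × markers after editing), so
either percentage convention can be checked against it.

## Genomic relationships

VanRaden column-centering: `z_ij = x_ij − 2p_j` with `p_j` the observed
frequency of the counted allele, and `G = ZZ′ / (2Σ p_j(1−p_j))`.
Monomorphic markers contribute nothing to numerator or denominator and are
excluded from the sum. A missing dosage contributes 0 after centering
(mean imputation) under the default `mean_impute` policy; the
`require_complete` policy refuses missing cells and points to the
imputation module — in the full pipeline G is computed after imputation, so
it never sees missing data. G is stored as computed; a ridge `εI` with
`ε = 1e−6 × mean(diag G)` is added only where G must be inverted, because
near-duplicate lines make G numerically singular. Note that
sample-frequency centering makes `Z′1 = 0`, so G always has a zero
eigenvalue: the ridge is not an optional nicety. The summary reports both
the off-diagonal-only and all-entries mean relationship (the phrase
"average relationship" is ambiguous between them), plus line × line block
means and the closest/farthest line pairs.

## Liability-threshold G-BLUP

The classifier is a Bernoulli GLMM with logit link: liability
`l = 1μ + Xg + e`, `g ~ N(0, Gσₐ²)`, residuals logistic with scale 1
(variance π²/3 ≈ 3.2899, displayed as 3.29), class `y = 1` iff `l > 0`.
Heritability on the liability scale is `h² = σₐ²/(σₐ² + π²/3)`;
`variance_from_h2` is the exact inverse, and the two compose to the
identity on [0, 1).

Fitting maximizes the Laplace-approximate marginal likelihood:

* **Inner loop** — Newton optimization of the penalized log-likelihood over
  (μ, g) jointly, with the design X mapping phenotyped records to their g
  entries. Unphenotyped individuals carry no records but stay in g, so the
  mode gives them the conditional-mean BLUP `G₂₁G₁₁⁻¹ĝ_train` exactly (a
  unit test asserts this identity). Gradient tolerance 1e−8 with
  step-halving; when the conditioning of G caps the reachable gradient norm
  the loop detects the stall and accepts the mode if the gradient is below
  1e−5 (without this, near-duplicate lines spin the solver at machine
  precision).
* **Laplace correction** — `−½ log det(I + σₐ² W^{1/2} G_oo W^{1/2})`
  evaluated on the phenotyped block only, with W the logistic weights at
  the mode.
* **Outer loop** — bounded scalar optimization of σₐ² on the log scale over
  [1e−6, 1e4], tolerance 1e−6, warm-starting the inner loop. An optimum
  within 1% of the upper bound flags quasi-separation and marks the fit
  non-converged.

In `fixed_h2` mode σₐ² is set to `h²/(1−h²)·π²/3` and only (μ, g) are
estimated — used for the forced-heritability sensitivity sweep. The
standard error of h² comes from the numerical curvature of the profile
log-likelihood via the delta method, `SE(h²) = c/(σ+c)² · SE(σₐ²)` with
`c = π²/3`; it is an observed-information approximation and is not expected
to match REML-package internals numerically.

The Laplace approximation is validated against tensor-product
Gauss–Hermite integration of the exact marginal likelihood on a
3-individual problem. The check runs at σₐ² = 0.1, where the approximation
error is well below 1e−3; the error grows with σₐ² (≈1e−2 at σₐ² = 1),
which is an intrinsic property of Laplace for Bernoulli data, not an
implementation artifact.

**Classification** uses `p = logistic(μ + gᵢ)` with the rule "high iff
p > 0.5"; a tie (p exactly 0.5) classifies low. Probabilities use the BLUP
point estimate of g, not an integral over its uncertainty.

**Model comparison** uses the likelihood-ratio statistic against the
intercept-only Bernoulli model (the σₐ² → 0 limit of the marginal
likelihood, so the two deviances are on the same scale). Because σₐ² = 0
lies on the parameter boundary, the null reference is the 50:50 mixture of
a point mass at zero and χ²₁: `p = 0.5·P(χ²₁ > stat)`. Small negative
statistics (≤ 1e−3) arising from the bounded variance search under the null
are clamped to zero; larger ones raise a convergence error. Calibration is
verified empirically: the empirical type-I error over 200 null populations
(n = 240, 30 lines of 8) stays inside the binomial 95% interval around the
nominal 5%. The mixture reference is asymptotic — on much smaller or weakly
structured panels the test runs conservative.

**RR-BLUP equivalence.** With `σ_b² = σₐ²/denom` and `G = ZZ′/denom` of
full rank, ridge-penalized logistic regression on marker dosages yields
`Z·b̂` identical to the G-BLUP mode (machine precision in the tests). The
sample-centered GRM is rank-deficient (see above), so the equivalence test
builds G from the uncentered −1/0/1 coding, where `ZZ′` is full rank for
more markers than samples.

## Cross-validation

Per repeat, a fresh uniform random partition into k folds with sizes
differing by at most one (123 into 5 gives 24/24/25/25/25). Per fold, test
phenotypes are set missing, the model refitted on the remainder — σₐ²
re-estimated per training set unless fixed, with a flag to freeze it for
speed — and the held-out plants classified. Error is reported both as the
mean over fold-level error rates and as the pooled count ratio; with
unequal folds these differ by at most 1/min-fold-size. Folds are not
stratified by class or line by default (an option exists). Training folds
containing a single class are skipped with a warning and counted, not
imputed. The GRM is computed once on all samples and reused across folds:
relationships are phenotype-free, so no label leakage. A per-line ledger
records every misclassified test observation with its line, supporting the
observation that errors concentrate in lines closely related to lines of
the opposite class.

## Association scan and LD

The scan fits `logit(p) = μ + β·dosage` per marker by Newton ML (50
iterations, steps damped near separation). |β| > 10 flags quasi-separation
and reports β at the cap; monomorphic markers are flagged and excluded from
summaries. No multiple-testing correction: the scan is descriptive (effect
magnitudes), not an inference procedure. "Large-effect" markers are the
top-q quantile of |β| (default 10%) — the analysis needs a set, not a
significance call.

LD is the squared Pearson correlation of dosage vectors (composite
genotypic r², the standard unphased estimator), invariant to allele-label
flips. Summaries average r² over all distinct pairs, over pairs sharing a
scaffold, and over the large-effect set. Since scaffold order is unknown,
"within-scaffold" is the finest positional stratum available; adjacency
chains are deliberately not constructed.

## Imputation and the masking experiment

Missing calls at a marker are predicted from the k most LD-correlated
markers on the same scaffold (default k = 5, informative means r² ≥ 0.1
on ≥ 5 jointly observed samples), via ordinary least squares of dosage on
the observed neighbors, rounded to the nearest genotype with ties toward
the heterozygote. Markers with no informative neighbor fall back to the
modal genotype, so on panels of mutually independent markers the imputer
reduces exactly to the modal baseline (asserted in a test). Between-scaffold
LD is never used. This is a deliberately simple scaffold-conditional
regression imputer, not a haplotype HMM; the masking experiment design is
the point, and the imputer is documented and exchangeable (any callable
with the same signature can be scored).

The masking experiment extracts a complete panel, injects exactly
`round(f·cells)` uniformly random missing cells at each fraction f (default
1, 2, 3, 5, 10, 20%; 5 replicates each; draws that would blank an entire
marker or sample are rejected), imputes, and scores the exact-genotype
(0/1/2) match rate over the masked cells only. The empirical accuracy curve
is then interpolated linearly at any observed missing rate inside the
measured range (extrapolation is refused). Linear interpolation is an
assumption; the curve is flat up to ~10% missingness in practice, so the
choice is immaterial there.

## Synthetic populations

The generator reproduces the statistical structure the estimators care
about:

* **LD**: per scaffold, haplotype alleles come from thresholding a Gaussian
  AR(1) latent process (correlation `within_scaffold_rho`, default 0.9),
  independent across scaffolds. A Gaussian copula gives exact control of
  block correlation at a tiny fraction of the cost of coalescent
  simulation; the artifact tests estimators, not population-genetic
  realism.
* **Line structure**: each line owns two founder haplotypes per scaffold;
  plants inherit random founder copies with a small per-allele flip
  probability (default 0.01), giving the high within-line relatedness of
  inbred panels.
* **Trait**: an oligogenic liability — n_qtl markers (default 10) clustered
  on a few scaffolds (default 3), effect signs random, magnitudes uniform
  in [0.5, 1.5]× a base size (or exactly equal with
  `qtl_effect_dist="equal"`), genetic values rescaled so the realized
  `Var(g)/(Var(g)+π²/3)` equals `target_h2` exactly. Liability
  `l = μ + g + e` with standard logistic e; class = 1 iff l > 0.
* **Classes and lines**: lines are ranked by founder genetic merit at the
  QTL; the top `n_lines_high` become high-vigor and receive the configured
  high-line sample counts, so both the 15/3 line split and the 100/24
  sample split hold exactly. By default the phenotype is assigned at line
  level (constant within line, as in real vigor panels); the
  individual-liability mode serves parameter-recovery simulations. The
  clean threshold at liability 0 is a simplification of the subjective
  visual scoring used in practice.
* **Defects on demand**: exact duplicate samples, and MCAR missingness at
  an exact cell count (3.14% of a 123 × 191 panel is 738 cells).

`beet_qc_fixture` additionally engineers exactly one duplicated
sample, one marker at call rate 0.80 and sixteen markers at MAF ≈ 0.008
into a 124 × 192 panel, then verifies and repairs the background so no
other sample or marker sits near a filter threshold; the default QC
pipeline therefore retains exactly 123 samples × 175 markers, with the
designed removals the only removals.

What the generator does **not** emulate: genotyping error structure
(missingness is MCAR, real call failures cluster by assay), allele-frequency
spectra from real ascertainment, LD decay with physical distance (AR(1) in
marker order stands in for it), selection and drift history, and any
environment or batch effects on the phenotype. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not performance guarantees on any particular real panel.

## Study-condition sizes used in the checks

Chosen as the package's own test design, balancing statistical resolution
against runtime:

* Heritability recovery: 20 populations of n = 400 (40 lines × 10), 200
  SNPs on 10 scaffolds, 10 equal-magnitude QTL spread one per scaffold,
  `within_scaffold_rho = 0.99`, individual-level phenotypes, true
  h² = 0.8. The QTL are deliberately well-tagged: when causal loci are
  clustered and unequally weighted, the marker GRM misrepresents the
  genetic covariance and h² is attenuated (by ~0.1 in side experiments) —
  a real property of GBLUP on oligogenic traits worth knowing, but the
  recovery check is about the estimator, so it runs where the model is
  approximately well-specified. Even so, the median estimate sits slightly
  below the truth: exact maximum likelihood on 40 clusters shows the same
  finite-sample skew, and the Laplace approximation contributes a further
  ~0.03.
* Degradation sweep: one sugar-beet-like population, k = 5, 20 repeats, fixed
  h² ∈ {0.783, 0.5, 0.33, 0.2}; medians over the 100 fold errors.
* LRT calibration: 200 null populations of n = 240.
* LD and imputation checks: 10-scaffold block panels (120–150 plants),
  rho 0.9–0.95.

## Known limitations

* Laplace ML underestimates large liability variances for binary data;
  at h² ≈ 0.8 expect a few points of downward bias even in well-specified
  settings. A quadrature or MCMC refinement would remove it at
  substantially higher cost.
* The LRT mixture reference is asymptotic and conservative on very small
  panels.
* The imputer ignores between-scaffold LD and haplotype phase by design;
  on long-range-LD panels a haplotype-based imputer will beat it.
* No fixed covariates beyond the intercept, no multi-class phenotypes, no
  pedigree relationships, no multi-allelic markers.
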