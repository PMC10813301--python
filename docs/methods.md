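# Methods

## The analysis model

The pipeline estimates shared genetic signal between a conditioning
trait (age at menarche, AAM) and several principal metabolic traits
(T2DM status, BFP, FBG, HbA1c) from per-SNP association statistics
computed on two disjoint halves of one cohort. The split-sample design
means the two p-value vectors are independent under the global null,
which is what both the conditional Q-Q construction and the empirical
cFDR estimator implicitly assume; it also removes the shared-control
covariance that cFDR implementations otherwise have to adjust for,
which is why no such adjustment is implemented here.

### Association model

Quantitative traits are analyzed by per-SNP OLS with covariates and an
intercept (computed by residualizing both the trait and the dosages on
the covariate design — the Frisch–Waugh identity makes this exactly the
joint fit); the binary diabetes status by Newton–Raphson maximum-
likelihood logistic regression (relative log-likelihood tolerance 1e-8,
50 iterations max) with Wald tests. The AAM GWAS adjusts for age at
enrollment, BMI and K principal components; the metabolic GWASs for
education (ordinal-coded), BMI and the PCs. K = 10 by default
(conventional, configurable). The effect allele is the minor allele in
the analyzed half, so betas are comparable across halves. p-values are
two-sided throughout and floored at the smallest positive double rather
than reported as 0. Constant dosages and separated logistic fits are
flagged (`constant` / `separation`) instead of raising, so one bad SNP
cannot abort a genome-wide scan.

PCA operates on the column-standardized, mean-imputed dosage matrix
via an exact eigendecomposition of the smaller Gram matrix; each
component's sign is fixed by making its largest-magnitude SNP loading
positive, so results are bit-reproducible. The pipeline thins the panel
(every 10th SNP by default) for the PC computation, as is customary for
ancestry PCs.

### Hardy–Weinberg exact test

The SNP QC applies the conditional exact test: given the observed
allele counts, the probability of each attainable heterozygote count is
computed (in log space, normalized by a max-shift, stable at
biobank-scale counts) and the two-sided p-value sums all configurations
no more probable than the observed one, with a 1e-12 relative guard
against float ties. The test suite checks this against an independent
exact-integer enumeration built from factorials, exhaustively for every
configuration of up to 200 genotypes.

QC conventions: sample filters run first (genotype missingness >= 2% or
any missing analysis phenotype), then SNP statistics are recomputed on
the retained samples (missingness >= 2%, MAF < 0.01, HWE p < 1e-6,
boundaries as written). The order is a documented choice — common
practice, not a claim about any particular study's internals. The HWE
test uses all retained samples, not controls only.

### Conditional Q-Q and the deflection statistic

For conditioning thresholds t in {1, 0.1, 0.01, 0.001} (the classic
convention; configurable) the stratum {i : p1_i <= t} is sorted by the
principal p-value, and the curve plots observed −log10 p against the
expected uniform quantile −log10(r/(s+1)) (the mean of the r-th order
statistic; r/s would put the last point at infinity). The deflection
statistic scalarizes the "leftward shift": the mean of
(observed − expected) over the curve's upper decile of expected
quantiles, floored at 0 — exactly 0 on the diagonal and exactly 1 for a
curve offset by one −log10 unit. Null curves are judged against a
Dvoretzky–Kiefer–Wolfowitz simultaneous band on the p-value scale. No
LD pruning is applied before curve construction; with the block
simulator LD is short-ranged, and an option hook is left for real data.

### Empirical cFDR

`cfdr_i = p2_i · #{j: p1_j ≤ p1_i} / #{j: p1_j ≤ p1_i ∧ p2_j ≤ p2_i}`,
counting inclusive at both coordinates, so the denominator contains SNP
i itself and is never zero; the result is clipped to (0, 1]. Inputs
with p = 0 are rejected rather than floored — the estimator is not
defined there and silent flooring would hide upstream problems.
Properties that follow directly and are enforced by tests:

* `cfdr_i ≥ p2_i` (the conditional empirical CDF is ≤ 1) — this bound
  also holds in every row of the packaged published loci table;
* with a degenerate conditioning vector the estimator reduces exactly
  to the unconditional empirical FDR `p2_i · m / rank(p2_i)`;
* discoveries are called at cFDR < alpha with strict inequality.

The dominance counts are computed in O(m log m) with a Fenwick tree
over p2 ranks (numba-compiled, with a pure-Python fallback), processing
p1 tie-groups atomically; genome-wide panels run in well under a
second.

Two calibration facts shape how the estimator should be used. When the
conditioning trait is independent of the principal trait, the procedure
is approximately calibrated (mixture simulations at m = 100,000 give a
mean false-discovery proportion below the nominal level; the acceptance
suite allows up to 0.075 at alpha = 0.05). When the conditioning trait
is informative — the situation the method exists for — the uncorrected
empirical estimator is anticonservative: it buys extra true discoveries
at a realized FDP above alpha. This is a known property of the raw
estimator; the loci it reports should be read as an enrichment-ranked
candidate list, not as a set with guaranteed FDR.

The raw estimator is also only approximately monotone in p2: in sparse
tails, lowering one p-value can drop it below a dense cluster and
shrink its denominator to 1 faster than its numerator shrinks. The
`monotone_envelope` flag (off by default) replaces each estimate with
the minimum raw estimate over all SNPs with p2 at least as large, which
restores exact monotonicity; it is off by default because the plain
estimator is the standard form.

### Clumping

Greedy best-first: repeatedly take the unassigned SNP with the smallest
score (minimum cFDR across traits; ties broken by chromosome, position,
id) as an index, and assign to it every unassigned same-chromosome SNP
strictly within the window (500 kb, index-to-member) and with r²
strictly above the threshold (0.1) against the index. Assignment is
one-pass — a SNP joins the first index that claims it — so clumps
partition the significant set and the clump count estimates the number
of independent loci. r² is the squared Pearson correlation of dosages
on pairwise-complete samples (computed from the half-2 genotype panel
in full runs, or from a user-supplied pairwise table); an undefined r²
(monomorphic vector) counts as 0. The implementation is checked against
an independently written brute-force reference on hundreds of random
instances.

## The synthetic cohort generator

The generator emulates the *structure* the analysis consumes, not any
particular population's genetics:

* **Genotypes.** Per SNP, a minor-allele frequency uniform on
  (0.01, 0.5]; within each LD block the two haplotypes of an individual
  follow independent latent-Gaussian AR(1) processes (adjacent-SNP
  correlation `block_ld_rho`, default 0.8), with the allele carried iff
  the latent variable falls below the frequency quantile. Genotype =
  sum of two i.i.d. haplotypes, so HWE holds by construction; blocks
  are independent; blocks are laid out round-robin over 22 chromosome
  labels with 5 kb SNP spacing and 1 Mb gaps. An optional
  two-subpopulation mode shifts allele frequencies by ±0.1 in half the
  cohort to exercise the PCA covariates.
* **Phenotypes.** Disjoint causal sets (shared / trait-1-only /
  trait-2-only) at fractions (0.01, 0.005, 0.005) by default; effect
  sizes i.i.d. normal on standardized dosages, rescaled so the realized
  genetic variance equals the configured heritability (0.5 for both
  axes by default — literature-scale values for AAM and T2DM
  liability). AAM = 13.3 + 1.5 × (genetic + noise); the cohort mean is
  the reported 13.3 y and the SD is a free parameter set to 1.5 y. BFP,
  FBG and HbA1c add independent noise to one common trait-2 genetic
  axis and are mapped to field-typical scales (32 ± 7%, 95 ± 15 mg/dL,
  5.7 ± 0.6%). T2DM status is the liability-threshold indicator
  `liability > Φ⁻¹(1 − 0.0457)` with liability = trait-2 genetic value
  + noise (unit variance). Age, BMI and education are drawn
  independently of the genetics. The true causal ids, components and
  effect sizes are returned as a sidecar (and written as a separate
  file) so downstream stages never see truth.
* **Summary-statistic fast path.** Per-SNP z-scores from a
  four-component mixture (null / trait-1-only / trait-2-only / shared)
  with random-sign noncentrality (default 4), two-sided normal-tail
  p-values — this is what the m = 100,000 cFDR and Q-Q experiments run
  on, in seconds.

What the generator does **not** emulate: realistic recombination maps
or long-range LD, allele-frequency spectra, population admixture,
genotype-covariate correlation (BMI is independent of BFP), trait-2
phenotypes with distinct genetic bases (they share one axis), or
imputation artifacts. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
real-data pathologies.

### Calibration and the liability threshold

The disease threshold is the standard-normal quantile, which is exact
only insofar as the liability is normal. With very few causal SNPs the
genetic score is coarsely discrete and the realized prevalence can miss
the target by a few tenths of a percentage point; a side computation
with a smoothed tail estimator shows the deviation falls below ~0.1 pp
once the trait-2 causal set reaches ~75 SNPs. Calibration runs
(tests and `scripts/acceptance.py`) therefore use m = 5,000 SNPs
(75 trait-2 causal at the default fractions) at n = 100,000 — densely
polygenic enough for the normal-quantile threshold to be accurate,
small enough to run in about a minute.

## Numerical and design choices

* Determinism: every stage draws from `numpy.random.Generator` streams
  derived from the config seed; identical config + seed gives
  bit-identical outputs (enforced by tests, including byte-identical
  pipeline loci TSVs).
* Coordinates are 1-based inclusive throughout; VCF is natively 1-based
  so no conversion occurs.
* The number parser accepts machine scientific notation and the
  typeset form printed in publication tables ("3.68 × 10−54", unicode
  multiplication and minus signs, caret exponents, digit-grouped
  positions); the packaged 39-locus reference table is stored in the
  printed notation and parsed through the same code path.
* Non-divisible `n_snps`/`n_blocks` puts the remainder in the last
  block. Monomorphic SNPs: MAF 0 (excluded by QC), HWE p = 1.0 (the
  single attainable configuration), undefined LD treated as 0 for
  clumping, `constant` status in association.
* Test problem sizes: simulation-heavy checks run at the sizes stated
  in their docstrings (m = 100,000 for summary-statistic experiments,
  n = 100,000 for generator calibration, n = 2,000 × 10,000 SNPs for
  GWAS null calibration); the full-pipeline tests use concentrated
  shared architectures at n ≈ 1,000 so that discoveries exist at small
  sample size while the whole suite stays fast.

## Known limitations

* The uncorrected empirical cFDR's anticonservatism under informative
  conditioning (above) is inherent to the estimator, not a bug; no
  conjunctional (ccFDR) or Bayesian local-fdr variant is provided.
* The split-sample design is sometimes described as a Mendelian-
  randomization-style precaution; no MR estimate is computed anywhere
  in this pipeline, so none is implemented.
* Logistic GWAS is a per-SNP Newton loop (no mixed models, no score
  test shortcut); genome-scale binary GWAS is the slowest stage.
* Gene annotation of loci is a plain id→label lookup from a
  user-supplied table; no external database is queried.
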