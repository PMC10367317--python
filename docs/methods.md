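# Methods

## The problem

Rumen microbes ferment the feed a ruminant eats; the community's
composition is associated with methane emission, feed efficiency and
other performance traits, and is itself partly shaped by the host's
genome. Combining a host genomic relationship matrix (GRM) with a
metagenome relationship matrix (MRM) in a linear mixed model lets one
ask how much phenotypic variance each source explains — heritability
(h²) and microbiability (m²) — and whether adding the metagenome to a
standard genomic prediction improves accuracy. `holopred` implements
that analysis for metagenome profiles produced by restriction
enzyme-reduced representation sequencing (RE-RRS): cheap shallow
profiles in which each feature is either a 65-bp cut-site "tag"
(reference-free, RF) or a genus count from alignment hits
(reference-based, RB).

## Metagenome relationship matrices

Counts `c_ij` (sample i, feature j, J features) are smoothed and
converted to proportions

    p_ij = (c_ij + 1) / (sum_j c_ij + J),

then log10-transformed. Columns of `log10(P)` are z-scored either
globally (**L10**) or within each rumen-sample cohort (**CA**), and the
MRM is the sample-by-sample Pearson correlation of the standardized
rows. CA removes per-feature cohort location/scale differences, making
the matrix robust to batch-like cohort effects at the cost of
discarding between-cohort signal.

Numerical choices:

* z-scores use the sample SD (divisor n − 1); the result is identical
  up to a constant factor that cancels in the correlation, so the MRM is
  insensitive to this choice, but it is fixed and documented.
* Columns constant globally (L10) or within a cohort (CA) are set to 0
  rather than dropped, keeping the feature set identical across cohorts;
  a warning is emitted.
* Sample and feature orderings are canonicalized (lexicographic tag
  sort) so tables and matrices are byte-reproducible.
* The +1 smoothing breaks exact scale invariance of the chain; with row
  sums ≥ 10,000 the effect on MRM entries is below 0.01 (checked by
  test).

## Genomic relationship matrix

VanRaden method 1: with dosage matrix W (0/1/2) and allele frequencies
p_j, Z = W − 2p and G = ZZ' / (2 Σ p_j(1 − p_j)). Frequencies default
to observed column means; monomorphic SNPs are dropped (their
denominator term is 0) with a warning. No blending or bending is
applied; a ridge of 1e-8 × mean diagonal is added inside the REML solver
only if a Cholesky factorization fails, and that event is recorded.

## Profiling

* Quality trimming is the standard 3′ partial-sum algorithm (as in BWA
  and cutadapt's `-q`): walking from the 3′ end, accumulate
  (threshold − q) and cut at the maximum of the running sum. Threshold
  20, minimum retained length 40 bp. No adapter trimming — tags are
  5′-anchored.
* Samples with fewer than 100,000 post-QC reads are flagged failed
  (strict inequality).
* A tag is the first 65 bases of a read that starts with the PstI
  remnant TGCAG; tags containing N are excluded. Tags observed
  (count ≥ 1) in at least 25% of a group's samples are retained — the
  boundary is inclusive.
* Reference-based profiling consumes tabular alignment hits: per read,
  hits below bit-score 50 or below 90% of the read's best bit-score are
  discarded and the lowest common ancestor of the surviving genomes'
  lineages is assigned (MEGAN-style defaults; both thresholds are
  arguments). Only reads assigned exactly at genus rank are counted in
  the genus profile; others are tallied separately. The min-support
  parameter of some MEGAN versions is not implemented; with min
  support 1 the behaviour coincides.

## Trait derivations

* Gas traits are scaled within measurement lot:
  `scaled = value / lot_mean × grand_mean`, so every lot's mean equals
  the grand mean (absorbing time-off-feed differences).
* Methane ratio = CH4/(CH4 + CO2) in mM/Mol. Because mM/Mol is a mole
  ratio, gram measures are converted with molar masses 16.04 (CH4) and
  44.01 (CO2) by default; `basis="mass"` gives the plain mass ratio
  × 1000 for sensitivity analysis.
* FEC transform: ln(count + 50).
* RFI is the OLS residual of intake on metabolic weight
  (liveweight^0.75, the Kleiber exponent — the specific exponent is a
  documented choice), growth rate, and cohort/flock/pen classes. A
  rank-deficient design raises an error naming the aliased terms.

## Variance components (REML)

The model is y = Xb + g + m + e with g ~ N(0, G σg²),
m ~ N(0, M σm²), e ~ N(0, I σe²), g ⊥ m. Any subset of {g, m} can be
fitted. The restricted log-likelihood
−½[log|V| + log|X'V⁻¹X| + y'Py] is maximized by average-information
(AI) updates with step-halving; when an AI step proposes a negative
component or fails to increase the likelihood, an EM step
(σ² ← σ² + σ⁴(y'PKPy − tr(PK))/n) is taken instead, which is uphill and
keeps components positive. Start values split var(y) equally across
components.

* Convergence: max relative parameter change < 1e-6 and log-likelihood
  change < 1e-8; at most 200 iterations. Non-convergence is reported as
  a flag (`max-iter`), never silently.
* Boundary handling: a component whose update goes negative twice
  consecutively is pinned to 0 and the fit flagged `boundary`.
* Identifiability: a singular AI matrix (condition number > 1e12, e.g.
  G = M = I) yields flag `singular` with NaN standard errors.
* SEs of components come from the inverse AI matrix; SEs of h², m² and
  the combined share by the delta method.
* BLUPs: û = σ̂² K V⁻¹(y − Xβ̂) for each random term; predictions for
  unphenotyped individuals use the cross-relationship block,
  û_test = σ̂² K_test,train V_train⁻¹(y_train − X_train β̂) (verified
  against Henderson's mixed-model equations in tests).
* Fixed designs are treatment-coded with an intercept; aliased columns
  are dropped with a warning so the design is full rank.

The reference analysis for this model family used ASReml; this
implementation targets the same restricted likelihood, not bit-level
agreement with any particular solver.

## Cross-validation

Each cohort (animals of one flock/birth-year sampled in the same ~2-day
window) is a fold. Per fold, the G, M and G+M models are refitted on
the remaining cohorts and five components are evaluated on the held-out
animals: G_G, M_M, G_G+M, M_G+M and G+M_G+M (BV + MV from the joint
model). Accuracy is the correlation between prediction and the
phenotype adjusted for fixed effects — deliberately not divided by √h²,
so BV and MV accuracies are comparable as predictors of phenotype.
Bias is the slope of adjusted phenotype on prediction (1 = unbiased).

* Fixed effects for the adjustment are estimated on the training folds
  only (leakage-free). A held-out fixed-effect level unseen in training
  makes the adjustment inestimable and fails that fold with an explicit
  reason — contemporary groups nested inside a cohort are the practical
  case.
* Summaries are cohort-size-weighted means and SDs; the SD uses the
  reliability-weights estimator Σw(v−v̄)²·Σw/((Σw)²−Σw²), which reduces
  exactly to the ddof=1 SD under equal weights.
* Three weighted paired t-tests (t = d̄_w/(sd_w/√k), df = k − 1,
  k folds): MV accuracy > BV accuracy (one-sided); MV vs BV bias slopes
  differ (two-sided); MV |slope − 1| < BV's (one-sided). A zero
  weighted SD of the differences yields a degenerate statistic reported
  as ±inf with the limiting p-value. How exactly the original weighted
  paired test weighted mean and variance is not standardized; this
  formula is the package's documented choice.
* Folds smaller than 2, or folds that fail (non-convergence, constant
  predictions, inestimable adjustment), are excluded and reported;
  weights renormalize over the remaining folds.

## Synthetic data

The generator emulates the study design end to end so the estimators
can be validated against known truth:

* **Genotypes**: per SNP, p ~ U(maf_range) and dosage ~ Binomial(2, p)
  — HWE, no LD.
* **Microbiome**: per-feature log-abundance = baseline (SD 1.5, giving
  realistically skewed abundance distributions) + cohort shift
  (SD `cohort_sd`, default 1.0 — cohort as a major driver) +
  host-genetic term + unit noise. The genetic term is linear in a
  random 5% subset of standardized SNP dosages, rescaled so it
  contributes `microbiome_heritability` (default 0.25) of the
  non-cohort log-abundance variance. Counts are multinomial per sample
  over softmax abundances with lognormal depth (default median 30,000
  reads — comfortably above the failed-sample threshold scale used in
  shallow RE-RRS profiles while keeping simulation cheap). Cohorts are
  assigned round-robin then shuffled.
* **Phenotypes**: y = μ + brr + aod + β·bdev + cg + g + m + e with
  σp² = 1. Class effects are drawn N(0, 0.3²); g is a dense linear
  genomic term and m a dense linear function of *globally* standardized
  log10 proportions, each rescaled to hit h²_target and m²_target
  exactly in sample; e ~ N(0, 1 − h² − m²). By default the
  contemporary group cg is independent of cohort; `alias_cg_cohort`
  reproduces the cg/cohort confounding hazard of real validation
  designs.
* **Reads**: each tag is emitted `count` times, extended with random
  bases to the read length, with substitution errors only outside the
  65-base tag by default (tags are fixed-length consensus sequences;
  indels are not modelled). Error-free reads round-trip exactly
  through QC + tag extraction.

Because the metagenome phenotype effect is generated on the globally
standardized log-proportion scale, parameter-recovery experiments pair
it with the L10 MRM — the kernel that matches the generating scale. The
CA MRM deliberately removes the cohort-level part of the metagenome
signal, so its recovered m² is smaller by construction; that contrast
is scientific signal, not an estimator defect. What the synthetic data
does **not** emulate: linkage disequilibrium, pedigree structure,
compositional interactions between taxa, diet/age differences between
groups, overdispersed (non-multinomial) counts, or sequencing-depth
confounding with cohort. Passing tests therefore demonstrate estimator
correctness under a well-specified generative model, not robustness to
every feature of real rumen data.

## Verification problem sizes

The verification battery (also re-run by `scripts/acceptance.py`) uses:
n = 1000 animals, 500 SNPs, 1000 features, 8 cohorts and 20 replicates
for parameter recovery (mean ĥ², m̂², combined share); n = 400, 5
cohorts, 20 replicates for the cross-validated MV-vs-BV contrast and
null-trait checks; n = 1000, 5 cohorts, 20 replicates for BLUP bias
slopes. These sizes give Monte-Carlo error comfortably below the
decision bands while keeping a full run in a few minutes on one CPU.

## Known limitations

* One record per animal per analysis; repeated measures and permanent
  environmental effects are out of scope.
* No G×M interaction, no Bayesian alternatives, no multi-trait models.
* The AI-REML solver is dense (O(n³) per iteration); it is intended for
  study sizes in the thousands, not hundreds of thousands.
* LCA assignment assumes a single fixed-depth lineage table; ranks
  missing from a lineage are treated as absent rather than interpolated.
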