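# holopred

Hologenomic prediction for livestock: combine host SNP genotypes with
rumen metagenome profiles from restriction enzyme-reduced representation
sequencing (RE-RRS) to partition phenotypic variance and predict traits
such as methane emissions, residual feed intake, liveweight and
parasite resistance.

The package is for quantitative geneticists and microbiome researchers
who want to estimate, on their own or simulated data:

* **heritability** h² = σg²/σp² and **microbiability** m² = σm²/σp² from
  the linear mixed model

  ```
  y = Xb + g + m + e,   g ~ N(0, G σg²),  m ~ N(0, M σm²),  e ~ N(0, I σe²)
  ```

  where **G** is a genomic relationship matrix (VanRaden method 1) and
  **M** a metagenome relationship matrix — the sample × sample Pearson
  correlation of column-standardized log₁₀ feature proportions
  p_ij = (c_ij + 1)/(row sum + J), standardized globally (L10) or
  within sampling cohort (CA);

* **prediction accuracy and bias** of breeding values (BV), metagenome
  values (MV) and their sum by cohort-fold cross-validation, with
  cohort-size-weighted summaries and weighted paired t-tests.

It covers the whole path from data to answer: read QC and 65-bp
cut-site tag profiling (reference-free) or MEGAN-style
lowest-common-ancestor genus profiling of alignment hits
(reference-based), trait derivations (within-lot gas scaling, CH₄/(CH₄
+ CO₂) methane ratio, ln(FEC + 50), residual feed intake), relationship
matrices, AI-REML with EM fallback, BLUP, and cross-validation. A
synthetic-data generator with known variance partitioning makes every
stage testable end to end. See `docs/methods.md` for the model details
and design choices.

## Worked example

Simulate a 400-animal study with 5 sampling cohorts where the
metagenome explains twice as much variance as host genetics
(h² = 0.25, m² = 0.50), then estimate the components and cross-validate:

```python
import holopred as hp

cfg = hp.SimConfig(n_animals=400, n_snps=300, n_features=400, n_cohorts=5,
                   h2_target=0.25, m2_target=0.50, seed=7)
gt, counts, cohorts, pheno, truth = hp.simulate_dataset(cfg)

G = hp.build_grm(gt.dosages)
M = hp.build_mrm(hp.normalize_l10(hp.log_proportions(counts)))

spec = hp.ModelSpec(trait="y", fixed=["brr", "aod", "bdev", "cg"])
fit = hp.fit_mixed_model(pheno, spec, G=G, M=M)
summary = hp.run_validation(pheno, spec, G, M)
```

This prints (via the snippet in `fit`/`summary` inspection):

```
converged: converged after 9 iterations
  sigma2_animal     = 0.250 (SE 0.064)
  sigma2_metagenome = 0.868 (SE 0.138)
  sigma2_residual   = 0.188 (SE 0.050)
  h2        = 0.191 (SE 0.048)
  m2        = 0.665 (SE 0.057)
  combined  = 0.856 (SE 0.045)
          mean     sd
G_G      0.211  0.085
M_M      0.484  0.053
G_G+M    0.262  0.132
M_G+M    0.501  0.058
G+M_G+M  0.523  0.028
                        t  df       p
accuracy_MV_gt_BV  4.7110   4  0.0046
bias_MV_ne_BV     -0.3169   4  0.7672
absbias_MV_lt_BV   1.3981   4  0.1173
```

Reading it: the animal-genetic variance is estimated at 0.250 with
h² = 0.19 and m² = 0.67 on this single replicate (estimates center on
the generating 0.25/0.50 when averaged over replicates — the
reproduction script below measures exactly that). Cross-validated
accuracy of the metagenome value (M_M, 0.48) is more than double that
of the breeding value (G_G, 0.21), the joint G+M prediction is best
(0.52), and the first weighted paired t-test confirms MV > BV accuracy
(p = 0.005). Component labels read *component_model*: e.g. G_G+M is the
BV's accuracy when fitted jointly with M.

There is also a thin CLI mirroring the stages:

```sh
holopred simulate --seed 1 --outdir sim/
holopred grm --genotypes sim/genotypes.tsv --out grm.tsv
holopred mrm --counts sim/counts.tsv --normalization l10 --out mrm.tsv
holopred fit --model model.yaml --out fit.json
holopred validate --model model.yaml --out-prefix val
holopred profile-rf sample1.fastq sample2.fastq ... --out counts.tsv
```

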