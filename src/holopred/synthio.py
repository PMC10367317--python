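"""Synthetic genotypes, heritable cohort-structured microbiomes, phenotypes, reads.

Generates the full data layout of a hologenomic prediction study so every
downstream stage is testable without real data:

* HWE SNP dosages with configurable minor-allele-frequency range;
* microbiome count tables whose per-feature log-abundances carry a
  cohort shift, a host-genetic component (a sparse linear function of
  standardized SNP dosages) and independent noise, observed through
  multinomial sampling at a lognormal library depth;
* phenotypes composed of fixed effects (birth/rearing rank, age of dam,
  birth-date deviation, contemporary group), a genome-wide additive
  breeding value scaled to a target heritability, a metagenome effect
  (linear in standardized log10 feature proportions) scaled to a target
  microbiability, and Gaussian residual;
* optionally, single-end FASTQ reads that start at a restriction-site
  remnant, from which the profiling module can recover the counts.

The phenotypic variance is 1 by construction: the genetic and metagenome
components are rescaled to hit their target variance shares exactly in
sample, so parameter-recovery tests compare estimates against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import log_proportions
from .profiling import DEFAULT_REMNANT, TAG_LENGTH

__all__ = [
    "SimConfig",
    "SimTruth",
    "GenotypeMatrix",
    "simulate_genotypes",
    "assign_cohorts",
    "simulate_microbiome",
    "simulate_phenotypes",
    "simulate_dataset",
    "random_tags",
    "simulate_reads",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study design for the synthetic dataset.

    Defaults describe a cohort-structured flock of 1000 genotyped,
    rumen-sampled animals with a markedly microbiable trait
    (h2 = 0.25, m2 = 0.50), 500 SNPs, 1000 metagenome features and 8
    sampling cohorts.
    """

    n_animals: int = 1000
    n_snps: int = 500
    n_features: int = 1000
    n_cohorts: int = 8
    maf_range: tuple = (0.05, 0.5)
    h2_target: float = 0.25
    m2_target: float = 0.50
    microbiome_heritability: float = 0.25
    cohort_sd: float = 1.0
    feature_sd: float = 1.5        # spread of baseline feature abundances (log scale)
    snp_sparsity: float = 0.05     # fraction of SNPs affecting each feature
    depth_log_mean: float = np.log(30_000.0)
    depth_log_sd: float = 0.3
    fixed_effect_spec: dict = field(
        default_factory=lambda: {
            "brr_levels": 3,
            "aod_levels": 3,
            "cg_levels": 3,
            "effect_sd": 0.3,
            "bdev_beta": 0.2,
            "alias_cg_cohort": False,
        }
    )
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie strictly inside (0, 1)")
        if not (0.0 <= self.h2_target < 1.0 and 0.0 <= self.m2_target < 1.0):
            raise ValueError("h2 and m2 targets must lie in [0, 1)")
        if self.h2_target + self.m2_target >= 1.0:
            raise ValueError("h2_target + m2_target must be < 1")
        if not 0.0 <= self.microbiome_heritability <= 1.0:
            raise ValueError("microbiome_heritability must lie in [0, 1]")
        if self.cohort_sd < 0:
            raise ValueError("cohort_sd must be non-negative")
        if self.n_cohorts < 2:
            raise ValueError("at least 2 cohorts are required")
        if self.n_animals < 2 * self.n_cohorts:
            raise ValueError("every cohort must receive at least 2 animals")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    true_breeding_values: pd.Series = None
    true_metagenome_values: pd.Series = None
    true_sigma_g2: float = np.nan
    true_sigma_m2: float = np.nan
    true_sigma_e2: float = np.nan
    feature_effects: np.ndarray = None
    fixed_effect_values: dict = None


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosages in {0,1,2} with generating allele frequencies."""

    dosages: pd.DataFrame
    freqs: np.ndarray

    @property
    def ids(self) -> list:
        return list(self.dosages.index)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (observed mean/SD), constant cols -> 0."""
        w = self.dosages.to_numpy(dtype=float)
        mu = w.mean(axis=0)
        sd = w.std(axis=0, ddof=1)
        z = np.zeros_like(w)
        ok = sd > 0
        z[:, ok] = (w[:, ok] - mu[ok]) / sd[ok]
        return z


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genotypes(
    n_animals: int, n_snps: int, maf_range=(0.05, 0.5), seed: int = 0
) -> GenotypeMatrix:
    """HWE dosages: per SNP j, p_j ~ U(maf_range) and dosage ~ Bin(2, p_j)."""
    if n_animals < 2 or n_snps < 1:
        raise ValueError("need n_animals >= 2 and n_snps >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("maf_range must lie strictly inside (0, 1)")
    rng = _rng(seed, 0)
    p = rng.uniform(lo, hi, size=n_snps)
    w = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.int8)
    ids = [f"A{i:05d}" for i in range(n_animals)]
    snps = [f"snp{j:05d}" for j in range(n_snps)]
    return GenotypeMatrix(
        dosages=pd.DataFrame(w, index=ids, columns=snps), freqs=p
    )


def assign_cohorts(n_animals: int, n_cohorts: int, seed: int = 0) -> np.ndarray:
    """Round-robin cohort labels by animal index, then seeded shuffle."""
    labels = np.array([f"C{i % n_cohorts:02d}" for i in range(n_animals)])
    _rng(seed, 1).shuffle(labels)
    return labels


def simulate_microbiome(
    genotypes: GenotypeMatrix, cfg: SimConfig
) -> tuple[pd.DataFrame, np.ndarray, SimTruth]:
    """Cohort-structured, partially host-heritable microbiome counts.

    Per-feature log-abundance = baseline + cohort shift (SD ``cohort_sd``)
    + host-genetic term (sparse linear in standardized dosages, scaled to
    ``microbiome_heritability`` of the non-cohort variance) + unit-scaled
    noise.  Per-sample counts are multinomial over features with a
    lognormal total.

    Returns
    -------
    (counts, cohorts, truth_fragment) : count table (animals x features),
    cohort label per animal, and a SimTruth carrying the per-feature
    phenotype effect sizes used later by :func:`simulate_phenotypes`.
    """
    n = genotypes.n_animals
    f = cfg.n_features
    rng = _rng(cfg.seed, 2)
    cohorts = assign_cohorts(n, cfg.n_cohorts, cfg.seed)
    cohort_levels = sorted(set(cohorts))

    base = rng.normal(0.0, cfg.feature_sd, size=f)
    cohort_eff = rng.normal(0.0, cfg.cohort_sd, size=(len(cohort_levels), f))
    cidx = np.array([cohort_levels.index(c) for c in cohorts])

    h = cfg.microbiome_heritability
    lam = np.tile(base, (n, 1)) + cohort_eff[cidx]
    if h > 0:
        z = genotypes.standardized()
        n_snp_eff = max(1, int(round(cfg.snp_sparsity * z.shape[1])))
        b = np.zeros((z.shape[1], f))
        for j in range(f):
            idx = rng.choice(z.shape[1], size=n_snp_eff, replace=False)
            b[idx, j] = rng.normal(0.0, 1.0, size=n_snp_eff)
        gen = z @ b
        sd = gen.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        gen = gen / sd * np.sqrt(h)
        lam += gen
    if h < 1:
        lam += rng.normal(0.0, np.sqrt(1.0 - h), size=(n, f))

    depth = np.round(np.exp(rng.normal(cfg.depth_log_mean, cfg.depth_log_sd, size=n)))
    if (depth < f).any():
        raise ValueError(
            "library depth parameters yield totals smaller than the number "
            "of features; profiles would be degenerate"
        )
    probs = np.exp(lam - lam.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(int(depth[i]), probs[i]) for i in range(n)]
    )
    table = pd.DataFrame(
        counts,
        index=genotypes.ids,
        columns=[f"feat{j:05d}" for j in range(f)],
        dtype=int,
    )
    truth = SimTruth(feature_effects=rng.normal(0.0, 1.0, size=f))
    return table, cohorts, truth


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    counts: pd.DataFrame,
    cfg: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes y = mu + brr + aod + b*bdev + cg + g + m + e.

    The breeding value g is a dense linear function of standardized
    dosages rescaled so its sample variance equals ``h2_target`` exactly;
    the metagenome effect m is a linear function of column-standardized
    log10 feature proportions rescaled to ``m2_target``; the residual is
    N(0, 1 - h2 - m2).  Realized components are stored in the returned
    SimTruth.
    """
    if list(genotypes.ids) != list(counts.index):
        raise ValueError("genotype and count-table ids do not align")
    n = genotypes.n_animals
    rng = _rng(cfg.seed, 3)
    spec = cfg.fixed_effect_spec
    truth = truth or SimTruth()

    # fixed part
    fe_vals = {}
    pheno = pd.DataFrame(index=counts.index)
    fixed = np.full(n, cfg.mu)
    for term, nlev in (("brr", spec["brr_levels"]), ("aod", spec["aod_levels"])):
        levels = [f"{term}{k}" for k in range(nlev)]
        lab = rng.choice(levels, size=n)
        eff = dict(zip(levels, rng.normal(0.0, spec["effect_sd"], size=nlev)))
        pheno[term] = lab
        fixed += np.array([eff[v] for v in lab])
        fe_vals[term] = eff
    bdev = rng.normal(0.0, 1.0, size=n)
    pheno["bdev"] = bdev
    fixed += spec["bdev_beta"] * bdev
    fe_vals["bdev_beta"] = spec["bdev_beta"]
    if spec.get("alias_cg_cohort", False):
        cg = assign_cohorts(n, cfg.n_cohorts, cfg.seed)
    else:
        cg = rng.choice([f"cg{k}" for k in range(spec["cg_levels"])], size=n)
    cg_levels = sorted(set(cg))
    cg_eff = dict(zip(cg_levels, rng.normal(0.0, spec["effect_sd"], size=len(cg_levels))))
    pheno["cg"] = cg
    fixed += np.array([cg_eff[v] for v in cg])
    fe_vals["cg"] = cg_eff

    # breeding value, scaled to the target variance share (sigma_p2 = 1)
    if cfg.h2_target > 0:
        z = genotypes.standardized()
        g = z @ rng.normal(0.0, 1.0, size=z.shape[1])
        g = (g - g.mean()) / g.std(ddof=1) * np.sqrt(cfg.h2_target)
    else:
        g = np.zeros(n)

    # metagenome effect on standardized log10 proportions
    if cfg.m2_target > 0:
        logp = log_proportions(counts).to_numpy()
        mu_ = logp.mean(axis=0)
        sd_ = logp.std(axis=0, ddof=1)
        sd_[sd_ == 0] = 1.0
        xstd = (logp - mu_) / sd_
        if truth.feature_effects is None:
            truth.feature_effects = rng.normal(0.0, 1.0, size=counts.shape[1])
        m = xstd @ truth.feature_effects
        m = (m - m.mean()) / m.std(ddof=1) * np.sqrt(cfg.m2_target)
    else:
        m = np.zeros(n)

    se2 = 1.0 - cfg.h2_target - cfg.m2_target
    e = rng.normal(0.0, np.sqrt(se2), size=n)

    pheno["y"] = fixed + g + m + e
    truth.true_breeding_values = pd.Series(g, index=counts.index)
    truth.true_metagenome_values = pd.Series(m, index=counts.index)
    truth.true_sigma_g2 = float(np.var(g, ddof=1))
    truth.true_sigma_m2 = float(np.var(m, ddof=1))
    truth.true_sigma_e2 = float(np.var(e, ddof=1))
    truth.fixed_effect_values = fe_vals
    return pheno, truth


def simulate_dataset(cfg: SimConfig):
    """Convenience wrapper: genotypes, counts, cohorts, phenotypes, truth."""
    gt = simulate_genotypes(cfg.n_animals, cfg.n_snps, cfg.maf_range, cfg.seed)
    counts, cohorts, truth = simulate_microbiome(gt, cfg)
    pheno, truth = simulate_phenotypes(gt, counts, cfg, truth)
    pheno["cohort"] = cohorts
    return gt, counts, cohorts, pheno, truth


def random_tags(
    n: int,
    length: int = TAG_LENGTH,
    remnant: str = DEFAULT_REMNANT,
    seed: int = 0,
) -> list:
    """Distinct random tag sequences starting with the cut-site remnant."""
    rng = _rng(seed, 4)
    tags = set()
    while len(tags) < n:
        body = "".join(rng.choice(_BASES, size=length - len(remnant)))
        tags.add(remnant + body)
    return sorted(tags)


def simulate_reads(
    counts: pd.DataFrame,
    tag_sequences: list,
    read_length: int = 101,
    remnant: str = DEFAULT_REMNANT,
    error_rate: float = 0.0,
    seed: int = 0,
    quality_char: str = "I",
) -> dict:
    """Single-end reads per sample: each tag emitted ``count`` times.

    Each read is its tag extended with random bases to ``read_length``;
    substitution errors are applied at ``error_rate`` per base outside
    the first ``tag_length`` bases, so the tag itself stays exact (the
    real protocol's tags are likewise anchored, error-free consensus
    sequences).  Qualities are a constant high Phred score.

    Returns
    -------
    dict sample_id -> list of (read_id, sequence, quality).
    """
    tag_len = len(tag_sequences[0]) if tag_sequences else 0
    for t in tag_sequences:
        if len(t) != tag_len or len(t) < TAG_LENGTH:
            raise ValueError(f"tag shorter than {TAG_LENGTH} bases: {t!r}")
        if not t.startswith(remnant):
            raise ValueError(f"tag does not start with remnant {remnant!r}: {t!r}")
    if read_length < tag_len:
        raise ValueError("read_length must be >= the tag length")
    if counts.shape[1] != len(tag_sequences):
        raise ValueError("one tag sequence per count-table column is required")
    rng = _rng(seed, 5)
    out = {}
    ext = read_length - tag_len
    for sample in counts.index:
        reads = []
        row = counts.loc[sample]
        for tag, c in zip(tag_sequences, row.to_numpy()):
            for _ in range(int(c)):
                seq = tag
                if ext > 0:
                    seq = seq + "".join(rng.choice(_BASES, size=ext))
                if error_rate > 0 and len(seq) > tag_len:
                    tail = np.array(list(seq[tag_len:]))
                    hit = rng.random(len(tail)) < error_rate
                    if hit.any():
                        tail[hit] = rng.choice(_BASES, size=int(hit.sum()))
                        seq = seq[:tag_len] + "".join(tail)
                rid = f"{sample}.{len(reads)}"
                reads.append((rid, seq, quality_char * len(seq)))
        out[sample] = reads
    return out


def write_fastq(reads: list, path) -> None:
    """Write (read_id, seq, qual) records as a Phred+33 FASTQ file."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
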