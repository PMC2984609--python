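"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: biallelic
SNPs under Hardy-Weinberg equilibrium with MAF above 1%, genotypes missing
completely at random per SNP, first-degree-relative families generated by
Mendelian gene drop from latent parent pairs, and lifespans produced by an
additive polygenic model

    lifespan_i = baseline + sum_j beta_j * g_ij + eps_i,   eps ~ N(0, sigma^2)

with the per-allele effects beta_j positive (so the longevity allele is the
minor allele at every causal SNP) and sigma chosen so the genetic component
accounts for ``target_heritability`` of the phenotypic variance.

The default configuration mirrors a mid-2000s family cohort with lifespan
follow-up: 1,173 individuals, 618 sibling families plus 162 singletons with
missing family identity, and an additive heritability of 25%.  The SNP count
defaults to a genome-wide 550,000 but every study in the test-suite and the
examples instantiates a smaller panel explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, make_phenotype_table
from .errors import ConfigError

_SNP_CHUNK = 4096


@dataclass
class EffectSizeDistribution:
    """Relative magnitudes of per-causal-SNP additive effects (years/allele).

    ``truncated_normal`` draws from a Gaussian with the given mean and sd
    truncated at zero, keeping every effect positive; with the default
    mean/sd ratio the effects are nearly equal, so an unweighted allele count
    recovers almost the whole additive genetic variance.  ``fixed`` uses the
    supplied values verbatim.  Drawn magnitudes are subsequently rescaled to
    hit the target heritability, so only their ratios matter.
    """

    kind: str = "truncated_normal"
    mean: float = 0.5
    sd: float = 0.125
    values: Optional[Sequence[float]] = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            vals = np.asarray(self.values, dtype=float)
            if len(vals) != n:
                raise ConfigError(
                    f"effect_size_distribution.values has {len(vals)} entries, need {n}")
            return vals.copy()
        if self.kind != "truncated_normal":
            raise ConfigError(f"effect_size_distribution.kind {self.kind!r} unknown")
        if self.sd <= 0:
            return np.full(n, float(self.mean))
        a = (0.0 - self.mean) / self.sd
        return stats.truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass
class SimulationConfig:
    n_individuals: int = 1173
    n_snps: int = 550_000
    n_causal: int = 100
    maf_range: tuple = (0.01, 0.5)
    call_rate_range: tuple = (0.8, 1.0)
    family_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.45, 3: 0.10})
    n_families: int = 618
    n_singletons: int = 162
    baseline_lifespan: float = 70.0
    lifespan_sd: float = 10.0
    target_heritability: float = 0.25
    effect_size_distribution: EffectSizeDistribution = field(
        default_factory=EffectSizeDistribution)
    random_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if self.n_snps <= 0:
            raise ConfigError("n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigError("n_causal must be between 0 and n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        lo, hi = self.call_rate_range
        if not (0 < lo <= hi <= 1.0):
            raise ConfigError("call_rate_range must satisfy 0 < low <= high <= 1")
        if not 0 <= self.target_heritability < 1:
            raise ConfigError("target_heritability must be in [0, 1)")
        if self.lifespan_sd <= 0:
            raise ConfigError("lifespan_sd must be positive")
        if self.n_families < 0 or self.n_singletons < 0:
            raise ConfigError("n_families and n_singletons must be non-negative")
        if self.n_families == 0 and self.n_singletons != self.n_individuals:
            raise ConfigError(
                "n_singletons must equal n_individuals when n_families is 0")
        in_families = self.n_individuals - self.n_singletons
        if self.n_families > 0 and in_families < self.n_families:
            raise ConfigError(
                "n_individuals - n_singletons must be at least n_families")
        sizes = list(self.family_size_distribution)
        probs = list(self.family_size_distribution.values())
        if self.n_families > 0:
            if any(s < 1 for s in sizes) or any(p < 0 for p in probs):
                raise ConfigError("family_size_distribution must map sizes>=1 to probabilities>=0")
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigError("family_size_distribution probabilities must sum to 1")
        if self.target_heritability > 0 and self.n_causal == 0:
            raise ConfigError(
                "target_heritability > 0 is unattainable with n_causal = 0")
        return self


@dataclass
class CausalTruth:
    """Ground truth of the additive model for parameter-recovery tests."""

    causal_snp_ids: np.ndarray
    effects: np.ndarray            # years per minor allele
    genetic_values: np.ndarray     # per-individual genetic component
    noise_sd: float
    realized_heritability: float


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: CausalTruth

    @property
    def causal_snp_ids(self):
        return self.truth.causal_snp_ids

    @property
    def realized_heritability(self) -> float:
        return self.truth.realized_heritability


def _streams(config: SimulationConfig) -> dict:
    children = np.random.SeedSequence(config.random_seed).spawn(6)
    names = ("families", "maf", "genotypes", "missing", "effects", "noise")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def assign_families(config: SimulationConfig) -> pd.DataFrame:
    """Map each individual to a family id or to None (missing family identity).

    Family sizes are drawn from ``family_size_distribution`` and then nudged
    (adding/removing one member of a random family at a time) until they sum
    to ``n_individuals - n_singletons`` exactly.
    """
    config.validate()
    rng = _streams(config)["families"]
    n = config.n_individuals
    individual_ids = np.array([f"I{i:06d}" for i in range(n)], dtype=object)
    family_ids = np.full(n, None, dtype=object)
    target = n - config.n_singletons
    if config.n_families > 0:
        size_options = np.array(sorted(config.family_size_distribution), dtype=int)
        probs = np.array([config.family_size_distribution[s] for s in size_options])
        sizes = rng.choice(size_options, size=config.n_families, p=probs / probs.sum())
        while sizes.sum() > target:
            shrinkable = np.flatnonzero(sizes > 1)
            if len(shrinkable) == 0:
                raise ConfigError(
                    "family_size_distribution cannot reach n_individuals - n_singletons")
            sizes[rng.choice(shrinkable)] -= 1
        while sizes.sum() < target:
            sizes[rng.integers(config.n_families)] += 1
        fam_labels = np.repeat(
            np.array([f"F{i:05d}" for i in range(config.n_families)], dtype=object),
            sizes)
        family_ids[:target] = fam_labels
    return pd.DataFrame({"individual_id": individual_ids, "family_id": family_ids})


def _founder_block(rng, maf_block, n):
    return rng.binomial(2, maf_block[None, :], size=(n, len(maf_block)))


def simulate_genotypes(config: SimulationConfig,
                       families: Optional[pd.DataFrame] = None) -> GenotypeMatrix:
    """Genotype matrix under HWE with gene-drop families and MCAR missingness.

    Individuals with a family id are generated as full siblings: two latent
    founder parents per family are drawn as Binomial(2, MAF) and each child
    receives one Bernoulli(parental dosage / 2) allele from each parent, so
    sib pairs have the expected first-degree dosage correlation of 1/2.
    Singletons are founder draws.  Missing calls are applied completely at
    random per SNP at rate 1 - call rate.
    """
    config.validate()
    streams = _streams(config)
    if families is None:
        families = assign_families(config)
    maf = streams["maf"].uniform(config.maf_range[0], config.maf_range[1], config.n_snps)

    fam_codes, fam_index = pd.factorize(families["family_id"].dropna())
    in_family = families["family_id"].notna().to_numpy()
    n_fam = len(fam_index)
    n = config.n_individuals
    child_of = np.full(n, -1, dtype=int)
    child_of[in_family] = fam_codes

    g_rng = streams["missing"]  # missingness stream
    geno_rng = streams["genotypes"]
    lo_cr, hi_cr = config.call_rate_range
    call_rate = g_rng.uniform(lo_cr, hi_cr, config.n_snps)

    dosages = np.empty((n, config.n_snps), dtype=np.float32)
    singleton_rows = np.flatnonzero(~in_family)
    family_rows = np.flatnonzero(in_family)
    fam_of_child = child_of[family_rows]

    for start in range(0, config.n_snps, _SNP_CHUNK):
        stop = min(start + _SNP_CHUNK, config.n_snps)
        maf_b = maf[start:stop]
        width = stop - start
        block = np.empty((n, width), dtype=np.float32)
        if len(singleton_rows):
            block[singleton_rows] = _founder_block(geno_rng, maf_b, len(singleton_rows))
        if n_fam:
            p1 = _founder_block(geno_rng, maf_b, n_fam)
            p2 = _founder_block(geno_rng, maf_b, n_fam)
            t1 = geno_rng.binomial(1, p1[fam_of_child] / 2.0)
            t2 = geno_rng.binomial(1, p2[fam_of_child] / 2.0)
            block[family_rows] = t1 + t2
        if hi_cr < 1.0 or lo_cr < 1.0:
            miss = g_rng.random((n, width)) >= call_rate[start:stop][None, :]
            block[miss] = np.nan
        dosages[:, start:stop] = block

    n_digits = max(6, len(str(config.n_snps)))
    snp_ids = np.array([f"rs{i:0{n_digits}d}" for i in range(config.n_snps)], dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=families["individual_id"].to_numpy(),
        snp_ids=snp_ids,
        chrom=np.ones(config.n_snps, dtype=int),
        pos=np.arange(1, config.n_snps + 1) * 1000,
        a1=np.full(config.n_snps, "A", dtype=object),
        a2=np.full(config.n_snps, "G", dtype=object),
    )


def simulate_lifespans(genotypes: GenotypeMatrix,
                       config: SimulationConfig,
                       families: Optional[pd.DataFrame] = None,
                       causal_snp_ids: Optional[Sequence] = None,
                       effects: Optional[Sequence[float]] = None,
                       noise_sd: Optional[float] = None):
    """Additive lifespans for an existing genotype matrix.

    Returns ``(phenotypes, truth)``.  Unless explicit ``effects`` are given,
    relative effect magnitudes are drawn from the configured distribution and
    rescaled so the genetic component's variance equals
    ``target_heritability * lifespan_sd**2``; the residual sd is then
    ``sqrt(1 - h2) * lifespan_sd``.  Missing causal genotypes contribute the
    SNP's observed mean dosage, so every individual has a defined phenotype.
    """
    config.validate()
    streams = _streams(config)
    rng_eff, rng_noise = streams["effects"], streams["noise"]
    h2 = config.target_heritability

    if causal_snp_ids is None:
        if config.n_causal > genotypes.n_snps:
            raise ConfigError("n_causal exceeds the number of SNPs in the matrix")
        idx = rng_eff.choice(genotypes.n_snps, size=config.n_causal, replace=False)
        idx.sort()
        causal_snp_ids = genotypes.snp_ids[idx]
    else:
        causal_snp_ids = np.asarray(list(causal_snp_ids), dtype=object)
        idx = genotypes.snp_indexer(causal_snp_ids)
    n_causal = len(idx)

    g = genotypes.dosages[:, idx].astype(np.float64)
    col_mean = np.nanmean(g, axis=0) if n_causal else np.zeros(0)
    if n_causal:
        nan_rows, nan_cols = np.nonzero(np.isnan(g))
        g[nan_rows, nan_cols] = col_mean[nan_cols]

    explicit = effects is not None
    if explicit:
        beta = np.asarray(effects, dtype=float)
        if len(beta) != n_causal:
            raise ConfigError(f"effects has {len(beta)} entries, need {n_causal}")
    else:
        beta = (config.effect_size_distribution.draw(n_causal, rng_eff)
                if h2 > 0 and n_causal else np.zeros(n_causal))

    genetic = g @ beta if n_causal else np.zeros(genotypes.n_individuals)
    if not explicit and h2 > 0:
        var_raw = genetic.var()
        if var_raw <= 0:
            raise ConfigError(
                "target_heritability > 0 is unattainable: genetic variance is zero")
        scale = np.sqrt(h2 * config.lifespan_sd ** 2 / var_raw)
        beta = beta * scale
        genetic = genetic * scale

    if noise_sd is None:
        noise_sd = (config.lifespan_sd * np.sqrt(1.0 - h2) if not explicit
                    else config.lifespan_sd)
    eps = rng_noise.normal(0.0, noise_sd, genotypes.n_individuals) if noise_sd > 0 \
        else np.zeros(genotypes.n_individuals)

    lifespan = config.baseline_lifespan + genetic + eps
    var_y = lifespan.var()
    realized = float(genetic.var() / var_y) if var_y > 0 else 0.0

    family_ids = None
    if families is not None:
        family_ids = (families.set_index("individual_id")["family_id"]
                      .reindex(genotypes.individual_ids).to_numpy())
    phenotypes = make_phenotype_table(genotypes.individual_ids, lifespan, family_ids)
    truth = CausalTruth(
        causal_snp_ids=np.asarray(causal_snp_ids, dtype=object),
        effects=beta,
        genetic_values=genetic,
        noise_sd=float(noise_sd),
        realized_heritability=realized,
    )
    return phenotypes, truth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: family assignment, genotypes and additive lifespans."""
    config.validate()
    families = assign_families(config)
    genotypes = simulate_genotypes(config, families=families)
    phenotypes, truth = simulate_lifespans(genotypes, config, families=families)
    return SyntheticCohort(genotypes=genotypes, phenotypes=phenotypes, truth=truth)


def unrelated_config(**kwargs) -> SimulationConfig:
    """Convenience: a config with no family structure (all singletons)."""
    cfg = SimulationConfig(**kwargs)
    return replace(cfg, n_families=0, n_singletons=cfg.n_individuals)
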