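# gendose

**Joint analysis of many small-effect alleles on human lifespan via a
"genetic dose – phenotypic response" relationship.**

Genome-wide association scans of lifespan find almost no individual SNP that
survives genome-wide significance, yet twin studies put the narrow-sense
heritability of human lifespan near 25%. One resolution is that longevity is
shaped by *many* alleles of small individual effect whose joint influence is
additive: count the "longevity alleles" an individual carries and lifespan
rises approximately linearly with that count. `gendose` implements this
analysis as a tested, reusable pipeline for statistical geneticists and for
anyone who wants to study (or teach) the selection-bias pitfalls of
polygenic scoring:

- **qc** — SNP-level quality control: call rate ≥ 80%, MAF > 1%,
  Hardy-Weinberg equilibrium p > 10⁻⁷ (Pearson χ², 1 df), with re-orientation
  of every SNP to minor-allele dosage coding.
- **scan** — per-SNP ordinary least squares of lifespan on 0/1/2
  minor-allele dosage, batched over the whole matrix; "longevity SNPs" are
  those with a positive slope and p ≤ a threshold (default 10⁻⁶).
- **dose** — the per-individual genetic dose `d_i = Σ_j g_ij` over a SNP
  panel (allele count; carrier count available), and the dose-response fit
  `lifespan_i = α₀ + α·d_i + ε_i`, both at the individual level (its R² is
  the variance in lifespan explained) and as the heteroscedasticity-corrected
  grouped fit: weighted least squares on dose-group mean lifespans with group
  sizes as weights — algebraically identical coefficients, group-level
  standard errors.
- **replicate** — the designs that separate a real polygenic signal from the
  winner's curse: one-per-family resampling (×10) with union/intersection
  panels, random-SNP negative controls, and split-half cross-prediction in
  family-disjoint halves (in-sample slope α vs cross-population slope α*).
- **simulate** — a synthetic cohort generator (HWE genotypes, gene-drop
  sibling families, missingness, additive lifespan model with calibrated
  heritability) so every stage is testable without access-restricted cohort
  data.
- **io / cli** — PLINK .bed/.bim/.fam and VCF readers/writers, phenotype
  CSV, and a `gendose` command with `simulate`, `qc`, `scan`, `score`,
  `replicate` and `run` (full pipeline with a reproducibility manifest).

## Model

For SNP *j* with minor-allele dosage `g_ij ∈ {0,1,2}` the scan fits
`lifespan_i = β₀ + β_j g_ij + ε_i` per SNP and selects the panel
`S = {j : β̂_j > 0, p_j ≤ 10⁻⁶}`. The genetic dose `d_i = Σ_{j∈S} g_ij`
then enters the dose-response regression `lifespan_i = α₀ + α d_i + ε_i`.
Because group variances scale as `σ²/n_g`, the grouped display fit weights
dose-group means by group size, which reproduces the individual-level OLS
line exactly. When `S` is selected and evaluated on the same individuals, α̂
is biased upward (winner's curse); the split-half design estimates the
honest cross-population slope α*.

## Worked example

```python
import gendose as g

cfg = g.SimulationConfig(
    n_individuals=5000, n_snps=2000, n_causal=100,
    n_families=1500, n_singletons=1550,
    family_size_distribution={2: 0.7, 3: 0.3},
    target_heritability=0.25, call_rate_range=(1.0, 1.0), random_seed=3)
cohort = g.simulate_cohort(cfg)

doses = g.genetic_dose(cohort.genotypes, list(cohort.causal_snp_ids))
fit = g.fit_dose_response(doses, cohort.phenotypes)
print(fit.intercept, fit.slope, g.variance_explained(fit))
```

prints (see `examples/03_dose_response.py`):

```
individual OLS: lifespan = 70.5 + 0.848 x dose  (slope p = 6.79e-290)
variance explained: 23.3% (planted narrow-sense heritability: 25.6%)
```

Each additional longevity allele adds ~0.85 years; the allele count alone
recovers ~23% of lifespan variance against the ~25% planted additive
heritability (the small gap is the cost of weighting all alleles equally).
`examples/04_replication_designs.py` shows the flip side on selected panels
— in-sample slopes average 1.86 yr/allele but only 1.23 replicate
cross-population (attenuation ratio 0.66, the winner's-curse share), while a
random control panel shows no dose-response at all (p = 0.19).

The other example scripts cover cohort simulation (`01`), QC + scan +
selection (`02`); each prints its numbers with a line on what they mean.

## Command line

```bash
gendose simulate --config sim.yaml --seed 5 --out-prefix cohort --vcf
gendose qc   --in cohort --out qc.tsv
gendose scan --in cohort --pheno cohort.pheno.csv --p-threshold 1e-6 --out scan.tsv
gendose score --in cohort --panel scan.tsv.panel.txt --pheno cohort.pheno.csv --out score
gendose replicate --in cohort --pheno cohort.pheno.csv --design split --k 10 --seed 3 --out rep
gendose run --config pipeline.yaml        # QC → scan → score → fit → replicate + manifest
```

Exit codes: 0 success, 2 validation/configuration error, 3 file-format error.

See `docs/methods.md` for the statistical model, simulator assumptions,
numerical choices and known limitations.
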