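# Methods

## The analysis

The pipeline tests whether lifespan responds linearly to the *number* of
small-effect "longevity" alleles an individual carries.

1. **QC.** Per SNP: call rate = non-missing fraction; MAF computed from
   non-missing genotypes with re-orientation (dosage → 2 − dosage) whenever
   the coded allele's frequency exceeds 0.5, so dosage always counts the
   minor allele; HWE tested by the Pearson χ² goodness-of-fit statistic
   (1 df, no continuity correction) against p², 2pq, q² at the sample allele
   frequency. Filter semantics are call rate ≥ 0.80 (inclusive), MAF > 0.01
   (strict) and HWE p > 10⁻⁷ (strict); monomorphic SNPs get HWE p = 1 and
   fail only the MAF filter. QC is applied once, to the full cohort, before
   any resampling design, which keeps SNP panels comparable across
   subsamples; the asymptotic χ² test (rather than an exact test) is the
   convention at genome scale and is what the thresholds were tuned for
   historically.

2. **Scan.** Per SNP, OLS of lifespan on numeric dosage over the
   pairwise-complete individuals (no imputation, no covariates), two-sided p
   from t with n−2 df. Genotype is treated as a single numeric covariate —
   the selection statistic is *the* slope, which only exists under additive
   coding; a 2-df genotype-category model is deliberately out of scope.
   Selection takes SNPs with a defined slope of the required sign (default
   positive) and p ≤ threshold; combined with the two-sided p this is an
   effective one-sided rate of half the threshold per SNP. Degenerate
   columns (monomorphic among used individuals, or n < 3) carry NaN
   statistics and are never selected. The batched implementation accumulates
   per-SNP moment sums (n, Σx, Σx², Σy, Σy², Σxy over the non-missing mask)
   in float64 and is element-wise identical to the per-SNP closed form;
   residual round-off is clipped at zero, and zero-residual fits are mapped
   to (t = 0, p = 1) for flat lines and (|t| = ∞, p = 0) otherwise.

3. **Dose.** Allele-count score `d_i = Σ_{j∈panel} g_ij` (default), or
   carrier count (number of panel SNPs with ≥ 1 minor allele). A missing
   genotype contributes 0 and is tallied per individual — the simplest rule,
   and the one the replication designs inherit; per-SNP mean imputation is
   available via `impute_mean=True`. The count is deliberately unweighted:
   the point of the analysis is that a bare count carries the signal.

4. **Dose-response.** Two fits of `lifespan = α₀ + α·d`:
   *individual_ols* over individuals — its R² is the "variance in lifespan
   explained" statistic compared against narrow-sense heritability; and
   *grouped_wls* — group individuals by integer dose, regress group mean
   lifespans on dose by WLS with group sizes as weights. Since
   Var(mean of group g) = σ²/n_g, size weights are exactly the
   inverse-variance weights: this is the heteroscedasticity correction for
   fitting the dose-group means, and it reproduces the individual-level OLS
   coefficients identically (a property the tests pin at 1e-8). The grouped
   R² describes group means and is *not* the variance-explained statistic;
   `variance_explained` refuses grouped fits. Sparse extreme-dose groups are
   retained — their small weights make them nearly inert.

5. **Replication designs.**
   - *One-per-family resampling*: one uniformly chosen member per family
     (singletons excluded by default), selection + fit per resample, k = 10
     resamples; the union of the per-run panels is intersected with the
     full-cohort panel to discard variants that only ever appear once.
     Per-run membership is recorded so the final panel's provenance is
     exportable.
   - *Negative control*: a random panel drawn without replacement from the
     QC-passed pool minus the longevity panel; its dose-response slope
     should be indistinguishable from zero.
   - *Split-half cross-prediction*: families are split uniformly at random
     into two halves (singletons attached to population 1 by default,
     configurable); a panel is selected in each half and its slope is
     estimated in-sample (α₁, α₂) and on the family-disjoint other half
     (α₁*, α₂*). Selection uses zero information from the opposite half,
     which the tests verify by recomputation. Table columns: experiment, N1,
     N2, N1SNP, N2SNP, and the four slopes each with its p-value. Slopes in
     this table use the individual-level fit by default (`fit_method`
     switches to the grouped fit); the two give identical slopes anyway.

   One master seed spawns per-experiment child seeds (all recorded in the
   outputs), so any single experiment is independently reproducible.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular population's genetics:

- **Genotypes.** Per SNP, MAF ~ Uniform(maf_range) (default 0.01–0.5; the
  paper-era genotyping regime is common variants only, and no allele
  frequency spectrum is assumed beyond that). Founders are Binomial(2, MAF)
  draws — HWE by construction. Families are sibships produced by Mendelian
  gene drop from two latent founder parents (each child receives one
  Bernoulli(parent dosage/2) allele per parent), giving the first-degree
  dosage correlation of 1/2 that the one-per-family and split-half designs
  exist to handle. Missingness is completely at random per SNP at rate
  1 − call rate, call rate ~ Uniform(call_rate_range) (default 0.8–1.0, so
  every SNP clears the 80% filter in expectation while exercising
  missing-data paths).
- **Lifespans.** `lifespan_i = baseline + Σ_j β_j g_ij + ε_i` with
  ε ~ N(0, σ²). Relative effect magnitudes β_j are drawn from a Gaussian
  truncated at zero (default mean 0.5, sd 0.125 yr/allele) — every causal
  minor allele is a longevity allele, matching the positive-slope selection
  convention — then rescaled so Var(Σβg) = h²·lifespan_sd², with
  σ = √(1−h²)·lifespan_sd. Realized heritability (sample genetic variance /
  sample lifespan variance) therefore calibrates to the target by
  construction. The small coefficient of variation of the effects (0.25) is
  a design choice: it keeps the *unweighted* allele count a near-sufficient
  statistic for the genetic value (count-score R² ≈ h²·E[β]²/E[β²] ≈
  0.94·h²), which is the regime the dose-response analysis presupposes. A
  wide effect distribution (e.g. half-normal, CV ≈ 0.76) would cap the
  count-score R² near 0.64·h² no matter the sample size — a scientifically
  interesting regime, but not the one being reproduced. Explicit per-SNP
  effects and noise sd can be supplied for controlled experiments. Missing
  causal genotypes contribute their SNP's observed mean dosage to the
  genetic value, so every individual has a phenotype. Because all effects
  are positive, the cohort mean lifespan exceeds `baseline_lifespan` (the
  expected lifespan at dose zero) by the mean genetic dose effect.
- **Families.** Family sizes are drawn from a configurable distribution
  (default {1: 0.45, 2: 0.45, 3: 0.10}) and nudged one member at a time
  until they sum exactly to n_individuals − n_singletons. The default
  design — 1,173 individuals, 618 families, 162 singletons with missing
  family identity — mirrors the family cohort the analysis was designed
  around. Lifespan defaults: baseline 70 yr, total sd 10 yr, h² = 0.25.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent, so panel sizes cannot be compared to real-data panel counts),
age-dependent mortality/censoring (lifespans are Gaussian and fully
observed, which is what a linear regression on lifespan exercises),
population stratification, informative missingness, parent genotypes
(sibships only) and gene–environment interaction. Passing tests show the
pipeline's statistics behave correctly under its own assumptions — not that
those assumptions hold in any real cohort.

## Numerical and design choices

- Dosages are stored as float32 (0/1/2 exactly representable, NaN =
  missing); all sufficient statistics are accumulated in float64 over SNP
  chunks of 4–8k, keeping a 20,000 × 5,000 study under ~0.5 GB.
- "Number of longevity SNPs contained in the genome" is read as the allele
  dosage sum (consistent with 0/1/2 regression coding); carrier counting is
  the ambiguity-resolving alternative and is exposed and tested.
- Whether the headline R² should come from the individual-level or the
  grouped regression is ambiguous in the source narrative; both are
  computed, and the individual-level one is labelled the variance-explained
  statistic (the grouped one is inflated by averaging).
- PLINK .bed/.bim/.fam support is implemented directly (the format is a
  3-byte magic plus 2-bit SNP-major codes); VCF reading goes through cyvcf2
  with multiallelic records skipped and counted, VCF writing is a minimal
  GT-only text writer. Readers never re-orient alleles.
- Statistical fits go through statsmodels (OLS/WLS); scipy provides the χ²
  and t tails. The batched genome scan is closed-form by design so it can be
  checked against `scipy.stats.linregress` as an independent oracle.
- Scale of the bundled studies: tests and the acceptance script run 20,000–
  50,000 SNP panels with 1,000–5,000 individuals — large enough for the
  null-calibration, winner's-curse and heritability-recovery phenomena to be
  unambiguous, and small enough to run in minutes. At n ≈ 1,173 the
  genome-wide threshold 10⁻⁶ selects essentially nothing under effects this
  small (the acceptance run reports that honestly); the relaxed thresholds
  (10⁻³–10⁻⁴) used for panel-building at this scale play the role that
  10⁻⁶ plays at the original cohort's power, and the strict/relaxed contrast
  is itself reported.

## Known limitations

- Without LD, selected panel sizes and union/intersection counts are not
  directly comparable to counts from dense genotyping arrays.
- The regression p-values ignore relatedness; on family cohorts under the
  global null they remain valid (lifespans are exchangeable), but with real
  effects the effective sample size is overstated — exactly the concern the
  one-per-family design addresses empirically.
- The grouped-WLS identity holds for size weights; other heteroscedasticity
  corrections (robust OLS variance) change SEs and are not implemented.
- `run_pipeline` re-reads genotypes per run; at genome scale (550k SNPs) a
  memory-mapped reader would be preferable.
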