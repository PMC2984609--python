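"""Genome-wide per-SNP simple linear regression of lifespan on dosage.

Each SNP is tested with ordinary least squares of lifespan on the 0/1/2
minor-allele dosage over the individuals genotyped at that SNP (pairwise
deletion, no covariates).  The two-sided p-value comes from the t
distribution with n-2 degrees of freedom.  "Longevity" SNPs are then
selected by sign and p-value threshold — by default a positive slope with
p <= 1e-6, an effective one-sided rate of 5e-7 per SNP.

``scan_all`` is a batched implementation over the whole matrix; it is
element-wise identical (to floating-point) to ``per_snp_regression`` applied
one SNP at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .errors import ValidationError

_SNP_CHUNK = 8192

SCAN_COLUMNS = ("snp_id", "n_used", "slope", "slope_se", "t_stat", "p_value")


@dataclass
class ScanResult:
    snp_id: object
    n_used: int
    slope: float
    slope_se: float
    t_stat: float
    p_value: float
    intercept: float = math.nan

    @property
    def defined(self) -> bool:
        return not math.isnan(self.slope)


@dataclass(frozen=True)
class SelectionRule:
    """Signed p-threshold rule for calling longevity SNPs."""

    p_threshold: float = 1e-6
    required_sign: str = "positive"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.required_sign not in ("positive", "negative", "any"):
            raise ValidationError("required_sign must be positive, negative or any")


def _finalize(n, slope, sxx_c, sxy_c, syy_c):
    """Slope SE / t / p from centered moments; handles degenerate columns."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy_c - slope * sxy_c
        rss = np.maximum(rss, 0.0)
        df = n - 2
        se = np.sqrt(rss / df / sxx_c)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    # Zero-residual cases: a flat response gives t=0, p=1; an exact non-flat
    # fit gives |t|=inf, p=0.
    exact = (se == 0) | np.isnan(t) & ~np.isnan(slope) & (rss == 0)
    flat = exact & (slope == 0)
    steep = exact & (slope != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(flat, 0.0, t)
        p = np.where(flat, 1.0, p)
        t = np.where(steep, np.inf * np.sign(slope), t)
        p = np.where(steep, 0.0, p)
    return se, t, p


def per_snp_regression(lifespans, genotype_column, snp_id=None) -> ScanResult:
    """OLS of lifespan on one SNP's dosage over pairwise-complete individuals.

    Degenerate columns (fewer than 3 usable individuals, or no genotype
    variance among them) yield a flagged result with NaN slope and p-value;
    such results are never selected.
    """
    y = np.asarray(lifespans, dtype=np.float64)
    x = np.asarray(genotype_column, dtype=np.float64)
    if y.shape != x.shape:
        raise ValidationError("lifespan and genotype vectors differ in length")
    use = ~np.isnan(x) & ~np.isnan(y)
    n = int(use.sum())
    if n < 3:
        return ScanResult(snp_id, n, math.nan, math.nan, math.nan, math.nan)
    xu, yu = x[use], y[use]
    sx, sy = xu.sum(), yu.sum()
    sxx_c = (xu * xu).sum() - sx * sx / n
    if sxx_c <= 0:
        return ScanResult(snp_id, n, math.nan, math.nan, math.nan, math.nan)
    sxy_c = (xu * yu).sum() - sx * sy / n
    syy_c = (yu * yu).sum() - sy * sy / n
    slope = sxy_c / sxx_c
    se, t, p = _finalize(np.array([n]), np.array([slope]), np.array([sxx_c]),
                         np.array([sxy_c]), np.array([syy_c]))
    intercept = (sy - slope * sx) / n
    return ScanResult(snp_id, n, float(slope), float(se[0]), float(t[0]),
                      float(p[0]), intercept=float(intercept))


def scan_all(matrix: GenotypeMatrix, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """One regression per SNP, batched over the matrix.

    Individuals are matched by id between the matrix and the phenotype table;
    per SNP only the individuals with a non-missing genotype enter the fit.
    Returns a DataFrame with columns snp_id, n_used, slope, slope_se, t_stat,
    p_value (NaN statistics for degenerate SNPs).
    """
    pheno = phenotypes.set_index("individual_id")["lifespan_years"]
    common_mask = pd.Index(matrix.individual_ids).isin(pheno.index)
    if not common_mask.any():
        raise ValidationError("no overlapping individuals between matrix and phenotypes")
    ids = matrix.individual_ids[common_mask]
    y = pheno.reindex(ids).to_numpy(dtype=np.float64)
    rows = np.flatnonzero(common_mask)

    n_snps = matrix.n_snps
    out = {
        "n_used": np.zeros(n_snps, dtype=int),
        "slope": np.full(n_snps, np.nan),
        "slope_se": np.full(n_snps, np.nan),
        "t_stat": np.full(n_snps, np.nan),
        "p_value": np.full(n_snps, np.nan),
    }
    y2 = y * y
    for start in range(0, n_snps, _SNP_CHUNK):
        stop = min(start + _SNP_CHUNK, n_snps)
        g = matrix.dosages[np.ix_(rows, np.arange(start, stop))].astype(np.float64)
        m = ~np.isnan(g)
        x = np.where(m, g, 0.0)
        n = m.sum(axis=0).astype(np.float64)
        sx = x.sum(axis=0)
        sxx = (x * x).sum(axis=0)
        sy = m.T @ y
        syy = m.T @ y2
        sxy = x.T @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx_c = sxx - sx * sx / n
            sxy_c = sxy - sx * sy / n
            syy_c = syy - sy * sy / n
            slope = sxy_c / sxx_c
        ok = (n >= 3) & (sxx_c > 0)
        slope = np.where(ok, slope, np.nan)
        se, t, p = _finalize(n, slope, sxx_c, sxy_c, syy_c)
        sl = slice(start, stop)
        out["n_used"][sl] = n.astype(int)
        out["slope"][sl] = slope
        out["slope_se"][sl] = np.where(ok, se, np.nan)
        out["t_stat"][sl] = np.where(ok, t, np.nan)
        out["p_value"][sl] = np.where(ok, p, np.nan)
    return pd.DataFrame({"snp_id": matrix.snp_ids, **out})


def select_longevity_snps(results, rule: SelectionRule = SelectionRule()):
    """SNP ids with a defined slope of the required sign and p <= threshold.

    ``results`` may be the scan DataFrame or a list of :class:`ScanResult`.
    Returns a sorted list of SNP ids (deterministic given inputs).
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([vars(r) for r in results]).rename(columns={"snp_id": "snp_id"})
    if len(df) == 0:
        raise ValidationError("empty scan results")
    slope = df["slope"].to_numpy(dtype=float)
    p = df["p_value"].to_numpy(dtype=float)
    defined = ~np.isnan(slope) & ~np.isnan(p)
    hit = defined & (p <= rule.p_threshold)
    if rule.required_sign == "positive":
        hit &= slope > 0
    elif rule.required_sign == "negative":
        hit &= slope < 0
    return sorted(df.loc[hit, "snp_id"].tolist())
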