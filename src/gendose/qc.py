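"""SNP-level quality control: call rate, minor allele frequency, HWE.

Filters follow the usual GWAS-era convention: a SNP is kept when its call
rate is at least the threshold (inclusive), its MAF strictly exceeds the MAF
threshold, and its Hardy-Weinberg equilibrium p-value strictly exceeds the
HWE threshold.  Defaults: call rate >= 0.80, MAF > 0.01, HWE p > 1e-7.

The HWE test is the Pearson chi-square goodness-of-fit test (1 df, no
continuity correction) of the observed genotype counts against the p^2, 2pq,
q^2 proportions at the sample allele frequency; monomorphic SNPs return p=1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .errors import ValidationError


@dataclass(frozen=True)
class QcThresholds:
    cr_threshold: float = 0.80
    maf_threshold: float = 0.01
    hwe_threshold: float = 1e-7

    def __post_init__(self):
        for name in ("cr_threshold", "maf_threshold", "hwe_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def call_rate(genotype_column) -> float:
    """Fraction of non-missing genotypes in one SNP column."""
    col = np.asarray(genotype_column, dtype=float)
    if col.size == 0:
        raise ValidationError("empty genotype column")
    return float(np.count_nonzero(~np.isnan(col)) / col.size)


def minor_allele_frequency(genotype_column):
    """MAF of one SNP column, plus whether the coded allele needs flipping.

    Returns ``(maf, needs_flip)``: ``needs_flip`` is True when the
    dosage-coded allele has frequency > 0.5, i.e. the column counts the major
    allele and should be re-oriented (dosage -> 2 - dosage).
    """
    col = np.asarray(genotype_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValidationError("all-missing genotype column")
    freq = obs.sum() / (2.0 * obs.size)
    needs_flip = bool(freq > 0.5)
    return float(min(freq, 1.0 - freq)), needs_flip


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Pearson chi-square HWE p-value from the three genotype counts."""
    counts = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    if (counts < 0).any():
        raise ValidationError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValidationError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)  # major-allele frequency
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dosages: np.ndarray):
    """Per-SNP counts of dosage 0/1/2 and missing, computed column-wise."""
    m = ~np.isnan(dosages)
    n_obs = m.sum(axis=0)
    n1 = np.count_nonzero(dosages == 1, axis=0)
    n2 = np.count_nonzero(dosages == 2, axis=0)
    n0 = n_obs - n1 - n2
    return n0, n1, n2, n_obs


def snp_qc_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized per-SNP QC statistics (no filtering applied).

    Columns: snp_id, call_rate, maf, hwe_p, needs_flip.  All-missing SNPs get
    call_rate 0 and NaN maf/hwe_p.
    """
    if matrix.n_snps == 0 or matrix.n_individuals == 0:
        raise ValidationError("empty genotype matrix")
    d = matrix.dosages
    n0, n1, n2, n_obs = _genotype_counts(d)
    n_total = matrix.n_individuals
    cr = n_obs / n_total

    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (2.0 * n2 + n1) / (2.0 * n_obs)  # coded-allele frequency
    needs_flip = freq > 0.5
    maf = np.where(needs_flip, 1.0 - freq, freq)

    # Pearson chi-square against HWE expectations at the sample frequency.
    with np.errstate(divide="ignore", invalid="ignore"):
        q = freq
        e0 = n_obs * (1 - q) ** 2
        e1 = n_obs * 2 * q * (1 - q)
        e2 = n_obs * q * q
        chi2 = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    hwe_p = stats.chi2.sf(chi2, df=1)
    mono = (q == 0.0) | (q == 1.0)
    hwe_p = np.where(mono, 1.0, hwe_p)
    hwe_p = np.where(n_obs == 0, np.nan, hwe_p)
    maf = np.where(n_obs == 0, np.nan, maf)

    return pd.DataFrame(
        {
            "snp_id": matrix.snp_ids,
            "call_rate": cr,
            "maf": maf,
            "hwe_p": hwe_p,
            "needs_flip": needs_flip & (n_obs > 0),
        }
    )


def apply_qc(matrix: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()):
    """Filter SNPs and re-orient surviving columns to minor-allele dosage.

    Returns ``(records, filtered_matrix)``.  ``records`` is the per-SNP QC
    table with a boolean ``passed`` column; the filtered matrix contains
    exactly the passing SNPs with dosage counting the minor allele (flipped
    columns have a1/a2 swapped).
    """
    records = snp_qc_table(matrix)
    passed = (
        (records["call_rate"] >= thresholds.cr_threshold)
        & (records["maf"] > thresholds.maf_threshold)
        & (records["hwe_p"] > thresholds.hwe_threshold)
    ).fillna(False)
    records = records.assign(passed=passed.to_numpy())

    keep = np.flatnonzero(records["passed"].to_numpy())
    out = matrix.subset_snps(keep)
    flip = records["needs_flip"].to_numpy()[keep]
    if flip.any():
        cols = np.flatnonzero(flip)
        out.dosages[:, cols] = 2.0 - out.dosages[:, cols]  # NaN stays NaN
        a1 = out.a1[cols].copy()
        out.a1[cols] = out.a2[cols]
        out.a2[cols] = a1
    return records, out
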