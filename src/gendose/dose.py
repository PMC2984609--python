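"""Genetic dose (longevity-allele count) and the dose-response regression.

The "genetic dose" of an individual is the number of longevity alleles it
carries over a selected SNP panel: in ``dosage`` mode the sum of minor-allele
counts (0/1/2 per SNP), in ``carrier`` mode the number of panel SNPs with at
least one minor allele.  Missing genotypes contribute 0 and are tallied.

The dose-response relationship is a straight line, lifespan = a + b * dose,
fitted two ways:

* ``individual_ols`` — OLS over individuals; its R^2 is the variance in
  lifespan explained by the panel (the quantity compared to narrow-sense
  heritability).
* ``grouped_wls`` — individuals are grouped by integer dose, group mean
  lifespans are fitted by weighted least squares with group sizes as weights.
  This is the heteroscedasticity-corrected display fit: group means have
  variance sigma^2 / n_g, so size weights are the inverse-variance weights,
  and the estimator reproduces the individual-level OLS coefficients exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix
from .errors import ValidationError

DOSE_MODES = ("dosage", "carrier")
FIT_METHODS = ("individual_ols", "grouped_wls")


def genetic_dose(matrix: GenotypeMatrix, panel, mode: str = "dosage",
                 impute_mean: bool = False) -> pd.DataFrame:
    """Per-individual longevity-allele count over the panel.

    Returns a DataFrame with columns individual_id, dose, n_snps_used,
    n_missing.  ``impute_mean=True`` replaces each missing genotype's
    contribution with the SNP's observed mean (dosage mode) or carrier
    frequency (carrier mode) instead of 0.
    """
    if mode not in DOSE_MODES:
        raise ValidationError(f"mode must be one of {DOSE_MODES}, got {mode!r}")
    panel = sorted(set(panel))
    n_ind = matrix.n_individuals
    if len(panel) == 0:
        dose = np.zeros(n_ind)
        n_missing = np.zeros(n_ind, dtype=int)
    else:
        idx = matrix.snp_indexer(panel)
        g = matrix.dosages[:, idx].astype(np.float64)
        miss = np.isnan(g)
        n_missing = miss.sum(axis=1)
        contrib = np.where(miss, 0.0, g if mode == "dosage" else (g >= 1))
        if impute_mean:
            with np.errstate(invalid="ignore"):
                col = (np.nanmean(g, axis=0) if mode == "dosage"
                       else np.nanmean(g >= 1, axis=0))
            col = np.nan_to_num(col)
            contrib = contrib + miss * col[None, :]
        dose = contrib.sum(axis=1)
    return pd.DataFrame(
        {
            "individual_id": matrix.individual_ids,
            "dose": dose,
            "n_snps_used": len(panel) - n_missing,
            "n_missing": n_missing,
        }
    )


@dataclass
class DoseResponseFit:
    """Straight-line fit of lifespan on genetic dose."""

    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_p: float
    r_squared: float
    n_individuals: int
    df_resid: float
    method: str
    group_table: Optional[pd.DataFrame] = field(default=None, repr=False)

    def slope_ci(self, alpha: float = 0.05):
        """Two-sided (1-alpha) confidence interval for the slope."""
        if math.isnan(self.slope) or self.df_resid <= 0:
            return (math.nan, math.nan)
        tq = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return (self.slope - tq * self.slope_se, self.slope + tq * self.slope_se)


def fit_dose_response(doses: pd.DataFrame, phenotypes: pd.DataFrame,
                      method: str = "individual_ols") -> DoseResponseFit:
    """Fit lifespan = intercept + slope * dose by the requested method.

    Individuals are matched by id; at least 3 distinct dose values are
    required.  ``grouped_wls`` also attaches the dose-group table
    (dose, n, mean_lifespan) used for the fit.
    """
    if method not in FIT_METHODS:
        raise ValidationError(f"method must be one of {FIT_METHODS}, got {method!r}")
    merged = doses.merge(
        phenotypes[["individual_id", "lifespan_years"]], on="individual_id", how="inner"
    )
    if len(merged) == 0:
        raise ValidationError("no overlapping individuals between doses and phenotypes")
    x = merged["dose"].to_numpy(dtype=float)
    y = merged["lifespan_years"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need at least 3 distinct dose values to fit a line")

    group_table = None
    if method == "individual_ols":
        res = sm.OLS(y, sm.add_constant(x)).fit()
    else:
        groups = (
            pd.DataFrame({"dose": x, "lifespan_years": y})
            .groupby("dose", sort=True)
            .agg(n=("lifespan_years", "size"), mean_lifespan=("lifespan_years", "mean"))
            .reset_index()
        )
        res = sm.WLS(
            groups["mean_lifespan"].to_numpy(),
            sm.add_constant(groups["dose"].to_numpy()),
            weights=groups["n"].to_numpy(dtype=float),
        ).fit()
        group_table = groups
    return DoseResponseFit(
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        intercept_p=float(res.pvalues[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        slope_p=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        n_individuals=len(merged),
        df_resid=float(res.df_resid),
        method=method,
        group_table=group_table,
    )


def variance_explained(fit: DoseResponseFit) -> float:
    """Variance in lifespan explained by the dose (individual-level R^2).

    Only defined for the individual-level fit: the grouped fit's R^2 refers
    to group means and is not the variance-explained statistic.
    """
    if fit.method != "individual_ols":
        raise ValidationError(
            "variance_explained requires an individual_ols fit; "
            f"got method {fit.method!r}")
    return fit.r_squared
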