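"""Validation designs: family de-duplication, negative controls, split-half.

Three designs guard the dose-response result against relatedness and
winner's-curse artefacts:

* one-per-family resampling, repeated k times, with the union of per-run
  panels and its intersection with the full-cohort panel;
* a negative-control panel of random SNPs drawn from the QC-passed pool with
  the longevity SNPs excluded;
* split-half cross-prediction: families are split into two halves, a panel
  is selected in each half and its dose-response slope is estimated both
  in-sample (alpha) and on the family-disjoint other half (alpha*), k times.

All randomness flows from one master seed that spawns per-run child seeds,
so any single experiment is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import List, Optional

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .dose import DoseResponseFit, fit_dose_response, genetic_dose
from .errors import ValidationError
from .scan import SelectionRule, scan_all, select_longevity_snps

TABLE2_COLUMNS = (
    "experiment", "N1", "N2", "N1SNP", "N2SNP",
    "alpha1", "alpha1_p", "alpha1_star", "alpha1_star_p",
    "alpha2", "alpha2_p", "alpha2_star", "alpha2_star_p",
)


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def family_dedup_resample(phenotypes: pd.DataFrame, seed,
                          include_singletons: bool = False) -> List:
    """One uniformly chosen member per family.

    Singletons (null family id) are excluded by default, mirroring a design
    that keeps exactly one genotyped member of each known family.
    """
    rng = _rng(seed)
    has_family = phenotypes["family_id"].notna()
    if not has_family.any():
        raise ValidationError("no family ids present in phenotype table")
    fam = phenotypes.loc[has_family]
    chosen = []
    for _, members in fam.groupby("family_id", sort=True):
        ids = members["individual_id"].tolist()
        chosen.append(ids[rng.integers(len(ids))])
    if include_singletons:
        chosen.extend(phenotypes.loc[~has_family, "individual_id"].tolist())
    return chosen


@dataclass
class ResampleRunResult:
    run_index: int
    seed: int
    individual_ids: List
    selected_snps: List
    fit: Optional[DoseResponseFit]


@dataclass
class UnionSelectionResult:
    union: List
    runs: List[ResampleRunResult]

    def membership(self) -> pd.DataFrame:
        """Which runs contributed each union SNP (provenance table)."""
        rows = [
            {"snp_id": s, "run_index": r.run_index}
            for r in self.runs for s in r.selected_snps
        ]
        df = pd.DataFrame(rows, columns=["snp_id", "run_index"])
        return (df.groupby("snp_id")["run_index"].agg(list).rename("runs")
                .reset_index().sort_values("snp_id", ignore_index=True))


def _child_seeds(seed, k):
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(k)]


def _safe_fit(matrix, panel, phenotypes, mode, method):
    """Dose-response fit, or None when the panel is empty/degenerate."""
    if len(panel) == 0:
        return None
    doses = genetic_dose(matrix, panel, mode=mode)
    try:
        return fit_dose_response(doses, phenotypes, method=method)
    except ValidationError:
        return None


def repeated_selection_union(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                             k: int = 10,
                             rule: SelectionRule = SelectionRule(),
                             seed: int = 0,
                             dose_mode: str = "dosage",
                             fit_method: str = "individual_ols") -> UnionSelectionResult:
    """k one-per-family resamples, panel selection and fit in each, unioned."""
    if k < 1:
        raise ValidationError("k must be at least 1")
    runs = []
    union: set = set()
    for run_index, child in enumerate(_child_seeds(seed, k)):
        ids = family_dedup_resample(phenotypes, child)
        sub = matrix.subset_individuals(ids)
        sub_pheno = phenotypes[phenotypes["individual_id"].isin(ids)]
        selected = select_longevity_snps(scan_all(sub, sub_pheno), rule)
        fit = _safe_fit(sub, selected, sub_pheno, dose_mode, fit_method)
        union.update(selected)
        runs.append(ResampleRunResult(run_index, child, ids, selected, fit))
    return UnionSelectionResult(union=sorted(union), runs=runs)


def intersect_sets(set_a, set_b) -> List:
    """Exact intersection, returned sorted by SNP identifier."""
    return sorted(set(set_a) & set(set_b))


def random_control_panel(qc_passed, excluded, size: int, seed) -> List:
    """Uniform random panel from the QC-passed pool minus the excluded set."""
    pool = sorted(set(qc_passed) - set(excluded))
    if size > len(pool):
        raise ValidationError(
            f"requested {size} control SNPs but pool has only {len(pool)}")
    rng = _rng(seed)
    chosen = rng.choice(len(pool), size=size, replace=False)
    return sorted(pool[i] for i in chosen)


@dataclass
class SplitReplicationRow:
    """One split-half experiment (one row of the replication table)."""

    experiment_index: int
    seed: int
    n1: int
    n2: int
    panel1: List
    panel2: List
    fit1: Optional[DoseResponseFit]        # panel 1 on population 1 (alpha1)
    fit1_star: Optional[DoseResponseFit]   # panel 1 on population 2 (alpha1*)
    fit2: Optional[DoseResponseFit]        # panel 2 on population 2 (alpha2)
    fit2_star: Optional[DoseResponseFit]   # panel 2 on population 1 (alpha2*)
    pop1_ids: List = field(repr=False, default_factory=list)
    pop2_ids: List = field(repr=False, default_factory=list)

    def as_record(self) -> dict:
        def s(fit):
            return (fit.slope, fit.slope_p) if fit is not None else (nan, nan)
        a1, p1 = s(self.fit1)
        a1s, p1s = s(self.fit1_star)
        a2, p2 = s(self.fit2)
        a2s, p2s = s(self.fit2_star)
        return {
            "experiment": self.experiment_index,
            "N1": self.n1, "N2": self.n2,
            "N1SNP": len(self.panel1), "N2SNP": len(self.panel2),
            "alpha1": a1, "alpha1_p": p1,
            "alpha1_star": a1s, "alpha1_star_p": p1s,
            "alpha2": a2, "alpha2_p": p2,
            "alpha2_star": a2s, "alpha2_star_p": p2s,
        }


@dataclass
class SplitReplicationResult:
    rows: List[SplitReplicationRow]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_record() for r in self.rows],
                            columns=list(TABLE2_COLUMNS))


def _split_families(phenotypes: pd.DataFrame, rng,
                    singletons_to: str = "pop1"):
    """Family-disjoint halves; singletons attached per ``singletons_to``."""
    fams = np.array(sorted(phenotypes.loc[phenotypes["family_id"].notna(),
                                          "family_id"].unique()), dtype=object)
    if len(fams) < 2:
        raise ValidationError("need at least 2 families to split")
    perm = rng.permutation(len(fams))
    half = (len(fams) + 1) // 2
    fams1 = set(fams[perm[:half]])
    fams2 = set(fams[perm[half:]])
    fam_col = phenotypes["family_id"]
    in1 = fam_col.isin(fams1)
    in2 = fam_col.isin(fams2)
    singles = fam_col.isna()
    if singletons_to == "pop1":
        in1 |= singles
    elif singletons_to == "pop2":
        in2 |= singles
    elif singletons_to == "split":
        flags = rng.random(int(singles.sum())) < 0.5
        sidx = np.flatnonzero(singles.to_numpy())
        in1 = in1.to_numpy()
        in2 = in2.to_numpy()
        in1[sidx[flags]] = True
        in2[sidx[~flags]] = True
        in1 = pd.Series(in1, index=phenotypes.index)
        in2 = pd.Series(in2, index=phenotypes.index)
    else:
        raise ValidationError("singletons_to must be pop1, pop2 or split")
    ids1 = phenotypes.loc[in1, "individual_id"].tolist()
    ids2 = phenotypes.loc[in2, "individual_id"].tolist()
    if not ids1 or not ids2:
        raise ValidationError("family split produced an empty population")
    return ids1, ids2


def split_half_replication(matrix: GenotypeMatrix, phenotypes: pd.DataFrame,
                           k: int = 10,
                           rule: SelectionRule = SelectionRule(),
                           seed: int = 0,
                           singletons_to: str = "pop1",
                           dose_mode: str = "dosage",
                           fit_method: str = "individual_ols") -> SplitReplicationResult:
    """k split-half cross-prediction experiments.

    Per experiment: families are split uniformly at random into two
    family-disjoint populations; a panel is selected by the genome-wide scan
    in each population; each panel's dose-response slope is fitted in-sample
    (alpha1, alpha2) and on the opposite population (alpha1*, alpha2*).
    Panel selection uses zero information from the opposite population.
    """
    if k < 1:
        raise ValidationError("k must be at least 1")
    rows = []
    for i, child in enumerate(_child_seeds(seed, k)):
        rng = np.random.default_rng(child)
        ids1, ids2 = _split_families(phenotypes, rng, singletons_to=singletons_to)
        m1 = matrix.subset_individuals(ids1)
        m2 = matrix.subset_individuals(ids2)
        ph1 = phenotypes[phenotypes["individual_id"].isin(ids1)]
        ph2 = phenotypes[phenotypes["individual_id"].isin(ids2)]
        panel1 = select_longevity_snps(scan_all(m1, ph1), rule)
        panel2 = select_longevity_snps(scan_all(m2, ph2), rule)
        rows.append(SplitReplicationRow(
            experiment_index=i + 1,
            seed=child,
            n1=len(ids1), n2=len(ids2),
            panel1=panel1, panel2=panel2,
            fit1=_safe_fit(m1, panel1, ph1, dose_mode, fit_method),
            fit1_star=_safe_fit(m2, panel1, ph2, dose_mode, fit_method),
            fit2=_safe_fit(m2, panel2, ph2, dose_mode, fit_method),
            fit2_star=_safe_fit(m1, panel2, ph1, dose_mode, fit_method),
            pop1_ids=ids1, pop2_ids=ids2,
        ))
    return SplitReplicationResult(rows=rows)
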