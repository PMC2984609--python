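"""Core in-memory containers: the genotype matrix and the phenotype table.

Genotypes are held as an individuals x SNPs array of minor-allele dosages
(0/1/2) with ``numpy.nan`` marking missing calls.  Storage is float32 (dosage
values are exactly representable); all statistics are computed in float64.
The phenotype table is a plain pandas DataFrame with columns
``individual_id``, ``family_id`` (None/NaN for singletons, i.e. individuals
with missing family identity) and ``lifespan_years``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

PHENO_COLUMNS = ("individual_id", "family_id", "lifespan_years")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    ``a1`` is the counted (dosage-coded) allele, ``a2`` the other allele.
    Positions are 1-based, as in .bim and VCF.  After QC re-orientation the
    counted allele is the minor allele at every SNP.
    """

    dosages: np.ndarray
    individual_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray = None
    pos: np.ndarray = None
    a1: np.ndarray = None
    a2: np.ndarray = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D individuals x SNPs array")
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n_ind, n_snp = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValidationError(
                f"individual_ids length {len(self.individual_ids)} != {n_ind} rows"
            )
        if len(self.snp_ids) != n_snp:
            raise ValidationError(f"snp_ids length {len(self.snp_ids)} != {n_snp} columns")
        if self.chrom is None:
            self.chrom = np.ones(n_snp, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, n_snp + 1, dtype=int)
        if self.a1 is None:
            self.a1 = np.full(n_snp, "A", dtype=object)
        if self.a2 is None:
            self.a2 = np.full(n_snp, "G", dtype=object)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("a1", self.a1), ("a2", self.a2)):
            if len(arr) != n_snp:
                raise ValidationError(f"{name} length {len(arr)} != {n_snp} SNPs")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_indexer(self, snp_ids) -> np.ndarray:
        """Column indices for the given SNP ids; raises naming any absent SNP."""
        index = pd.Index(self.snp_ids)
        snp_ids = list(snp_ids)
        locs = index.get_indexer(snp_ids)
        if (locs < 0).any():
            missing = [s for s, i in zip(snp_ids, locs) if i < 0]
            raise ValidationError(f"SNP not present in genotype matrix: {missing[0]!r}")
        return locs

    def individual_indexer(self, individual_ids) -> np.ndarray:
        index = pd.Index(self.individual_ids)
        individual_ids = list(individual_ids)
        locs = index.get_indexer(individual_ids)
        if (locs < 0).any():
            missing = [s for s, i in zip(individual_ids, locs) if i < 0]
            raise ValidationError(f"individual not present in genotype matrix: {missing[0]!r}")
        return locs

    def subset_snps(self, selector) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask, integer array or id list of SNPs."""
        sel = np.asarray(selector)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        elif np.issubdtype(sel.dtype, np.integer):
            idx = sel
        else:
            idx = self.snp_indexer(sel)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            individual_ids=self.individual_ids.copy(),
            snp_ids=self.snp_ids[idx].copy(),
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
            a1=self.a1[idx].copy(),
            a2=self.a2[idx].copy(),
        )

    def subset_individuals(self, selector) -> "GenotypeMatrix":
        sel = np.asarray(selector)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        elif np.issubdtype(sel.dtype, np.integer):
            idx = sel
        else:
            idx = self.individual_indexer(sel)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :].copy(),
            individual_ids=self.individual_ids[idx].copy(),
            snp_ids=self.snp_ids.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            a1=self.a1.copy(),
            a2=self.a2.copy(),
        )


def make_phenotype_table(individual_ids, lifespans, family_ids=None) -> pd.DataFrame:
    """Assemble and validate a phenotype table."""
    df = pd.DataFrame(
        {
            "individual_id": np.asarray(individual_ids, dtype=object),
            "family_id": (np.asarray(family_ids, dtype=object)
                          if family_ids is not None else None),
            "lifespan_years": np.asarray(lifespans, dtype=float),
        }
    )
    validate_phenotypes(df)
    return df


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"phenotype table missing column {col!r}")
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate individual_id {dup.iloc[0]!r} in phenotype table")
    bad = df["lifespan_years"].isna() | (df["lifespan_years"] <= 0)
    if bad.any():
        offender = df.loc[bad, "individual_id"].iloc[0]
        raise ValidationError(f"non-positive or missing lifespan for individual {offender!r}")
    return df
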