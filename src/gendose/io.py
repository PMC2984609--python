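"""Readers and writers for PLINK 1 binary, VCF and delimited tables.

Readers report the coded allele verbatim (A1 for PLINK, ALT for VCF);
re-orientation to minor-allele dosage is the QC stage's responsibility.
Positions are 1-based as native to .bim and VCF.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_phenotypes
from .errors import FormatError, ValidationError

log = logging.getLogger("gendose")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed, SNP-major
# 2-bit PLINK codes indexed by dosage of A1: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
_CODE_OF_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_OF_CODE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)


def write_plink(matrix: GenotypeMatrix, prefix, phenotypes: pd.DataFrame = None) -> None:
    """Write a .bed/.bim/.fam triplet (SNP-major bed, A1 = coded allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = pd.DataFrame({
        "chrom": matrix.chrom, "snp_id": matrix.snp_ids, "cm": 0,
        "pos": matrix.pos, "a1": matrix.a1, "a2": matrix.a2,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam_id = {}
    if phenotypes is not None:
        fam_id = dict(zip(phenotypes["individual_id"], phenotypes["family_id"]))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in matrix.individual_ids:
            fid = fam_id.get(iid)
            fid = iid if fid is None or pd.isna(fid) else fid
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")

    n_ind = matrix.n_individuals
    n_bytes = (n_ind + 3) // 4
    # dosage -> 2-bit code, individuals padded to a multiple of 4 with code 0
    d = matrix.dosages
    codes = np.full(d.shape, 0b01, dtype=np.uint8)  # missing
    for dose, code in _CODE_OF_DOSAGE.items():
        codes[d == dose] = code
    codes = codes.T  # SNP-major: (n_snps, n_ind)
    padded = np.zeros((matrix.n_snps, n_bytes * 4), dtype=np.uint8)
    padded[:, :n_ind] = codes
    packed = (padded[:, 0::4]
              | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4)
              | (padded[:, 3::4] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triplet into a dosage matrix (A1 counted)."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file {p}")
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    n_snps, n_ind = len(bim), len(fam)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"bad magic bytes in {bed_path}")
    n_bytes = (n_ind + 3) // 4
    expected = 3 + n_snps * n_bytes
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: size {len(raw)} does not match "
            f"{n_ind} individuals x {n_snps} SNPs (expected {expected})")
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, n_bytes)
    codes = np.empty((n_snps, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dosages = _DOSAGE_OF_CODE[codes[:, :n_ind]].T  # individuals x SNPs
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp_id"].to_numpy(dtype=object),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
    )


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Minimal uncompressed VCF with GT only; REF = a2, ALT = a1 (counted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(matrix.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in matrix.individual_ids) + "\n")
        d = matrix.dosages
        for j in range(matrix.n_snps):
            gts = "\t".join(
                gt_of.get(float(d[i, j]), "./.") if not np.isnan(d[i, j]) else "./."
                for i in range(matrix.n_individuals))
            fh.write(f"{matrix.chrom[j]}\t{matrix.pos[j]}\t{matrix.snp_ids[j]}\t"
                     f"{matrix.a2[j]}\t{matrix.a1[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT genotypes from a biallelic VCF; ALT is the counted allele.

    Multiallelic records are skipped (a count is logged).  Phase is ignored.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing VCF file {path}")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=object)
    rows, snp_ids, chrom, pos, a1, a2 = [], [], [], [], [], []
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(np.float32)  # 0/1/2, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        a1.append(var.ALT[0])
        a2.append(var.REF)
    if n_multi:
        log.warning("read_vcf: skipped %d multiallelic record(s) in %s", n_multi, path)
    if not rows:
        raise FormatError(f"no biallelic records with GT found in {path}")
    dosages = np.vstack(rows).T
    return GenotypeMatrix(dosages=dosages, individual_ids=samples,
                          snp_ids=np.asarray(snp_ids, dtype=object),
                          chrom=np.asarray(chrom), pos=np.asarray(pos, dtype=int),
                          a1=np.asarray(a1, dtype=object),
                          a2=np.asarray(a2, dtype=object))


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype table (individual_id, family_id, lifespan_years).

    Delimiter is sniffed between comma and tab; empty family_id becomes a
    null family (singleton).  Duplicate ids and non-positive lifespans are
    rejected with the offending value named.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing phenotype file {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype={
        "individual_id": str, "family_id": str})
    df = df.rename(columns=lambda c: c.strip())
    for col in ("individual_id", "family_id", "lifespan_years"):
        if col not in df.columns:
            raise ValidationError(f"phenotype file {path} missing column {col!r}")
    fam = df["family_id"]
    df["family_id"] = fam.where(fam.notna() & (fam.astype(str).str.strip() != ""),
                                other=None)
    df["lifespan_years"] = pd.to_numeric(df["lifespan_years"], errors="coerce")
    return validate_phenotypes(df[["individual_id", "family_id", "lifespan_years"]])


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = phenotypes.copy()
    out["family_id"] = out["family_id"].fillna("")
    out.to_csv(path, index=False)


def write_truth(truth, path) -> None:
    """Ground-truth TSV (snp_id, beta) for a simulated cohort."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"snp_id": truth.causal_snp_ids, "beta": truth.effects}).to_csv(
        path, sep="\t", index=False)
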