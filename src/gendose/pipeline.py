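"""End-to-end pipeline: QC -> scan -> select -> score -> fit -> replicate.

Every stage writes its artifact under the output directory and the run ends
with a JSON manifest recording inputs, thresholds, seeds, per-stage counts
and the SHA-256 of every output file — enough to reproduce the run
bit-identically from the same config and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix
from .dose import fit_dose_response, genetic_dose, variance_explained
from .errors import ConfigError
from .io import read_phenotypes, read_plink, read_vcf
from .qc import QcThresholds, apply_qc
from .replicate import (intersect_sets, random_control_panel,
                        repeated_selection_union, split_half_replication)
from .scan import SelectionRule, scan_all, select_longevity_snps

log = logging.getLogger("gendose")


@dataclass
class PipelineConfig:
    genotypes: str                       # PLINK prefix or .vcf path
    phenotypes: str
    out_dir: str
    seed: Optional[int] = None
    cr_threshold: float = 0.80
    maf_threshold: float = 0.01
    hwe_threshold: float = 1e-7
    p_threshold: float = 1e-6
    required_sign: str = "positive"
    dose_mode: str = "dosage"
    fit_method: str = "individual_ols"
    replication_designs: tuple = ()      # subset of ("dedup", "split", "control")
    k: int = 10
    control_panel_size: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field {sorted(unknown)[0]!r}")
        if "replication_designs" in raw and raw["replication_designs"] is not None:
            raw["replication_designs"] = tuple(raw["replication_designs"])
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        for d in self.replication_designs:
            if d not in ("dedup", "split", "control"):
                raise ConfigError(f"unknown replication design {d!r}")
        if self.replication_designs and self.seed is None:
            raise ConfigError("seed is required when replication designs are requested")
        return self


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_genotypes(spec: str) -> GenotypeMatrix:
    if str(spec).endswith(".vcf"):
        return read_vcf(spec)
    return read_plink(spec)


def run_pipeline(config: PipelineConfig,
                 matrix: GenotypeMatrix = None,
                 phenotypes: pd.DataFrame = None) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    ``matrix``/``phenotypes`` may be passed in-memory to skip file reading
    (the manifest then records the config paths verbatim).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = load_genotypes(config.genotypes)
    if phenotypes is None:
        phenotypes = read_phenotypes(config.phenotypes)

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    stage = manifest["stages"]

    # --- QC ---
    thresholds = QcThresholds(config.cr_threshold, config.maf_threshold,
                              config.hwe_threshold)
    records, qc_matrix = apply_qc(matrix, thresholds)
    _write_tsv(records, out / "qc.tsv")
    stage["qc"] = {"snps_in": int(matrix.n_snps),
                   "snps_out": int(qc_matrix.n_snps)}
    log.info("qc: %d -> %d SNPs", matrix.n_snps, qc_matrix.n_snps)

    # --- scan + selection ---
    rule = SelectionRule(config.p_threshold, config.required_sign)
    results = scan_all(qc_matrix, phenotypes)
    _write_tsv(results, out / "scan.tsv")
    panel = select_longevity_snps(results, rule)
    (out / "panel.txt").write_text("".join(f"{s}\n" for s in panel))
    stage["scan"] = {"snps_tested": int(len(results)),
                     "snps_selected": int(len(panel))}
    log.info("scan: %d tested, %d selected at p<=%g (%s)",
             len(results), len(panel), rule.p_threshold, rule.required_sign)

    # --- dose + fits ---
    doses = genetic_dose(qc_matrix, panel, mode=config.dose_mode)
    _write_tsv(doses, out / "dose.tsv")
    fits = {}
    if len(panel) > 0 and doses["dose"].nunique() >= 3:
        for method in ("individual_ols", "grouped_wls"):
            fit = fit_dose_response(doses, phenotypes, method=method)
            fits[method] = fit
            if fit.group_table is not None:
                _write_tsv(fit.group_table, out / "dose_groups.tsv")
        summary = pd.DataFrame([
            {"method": m, "intercept": f.intercept, "intercept_se": f.intercept_se,
             "slope": f.slope, "slope_se": f.slope_se, "slope_p": f.slope_p,
             "r_squared": f.r_squared, "n": f.n_individuals}
            for m, f in fits.items()])
        _write_tsv(summary, out / "fit.tsv")
        stage["fit"] = {
            "slope": fits["individual_ols"].slope,
            "slope_p": fits["individual_ols"].slope_p,
            "variance_explained": variance_explained(fits["individual_ols"]),
        }
    else:
        stage["fit"] = {"skipped": "panel empty or fewer than 3 distinct doses"}

    # --- replication designs ---
    qc_ids = list(qc_matrix.snp_ids)
    if "dedup" in config.replication_designs:
        res = repeated_selection_union(
            qc_matrix, phenotypes, k=config.k, rule=rule, seed=config.seed,
            dose_mode=config.dose_mode, fit_method=config.fit_method)
        (out / "union_panel.txt").write_text("".join(f"{s}\n" for s in res.union))
        _write_tsv(res.membership(), out / "union_membership.tsv")
        final = intersect_sets(res.union, panel)
        (out / "final_panel.txt").write_text("".join(f"{s}\n" for s in final))
        stage["dedup"] = {"k": config.k, "union_size": len(res.union),
                          "intersection_size": len(final),
                          "run_seeds": [r.seed for r in res.runs]}
        log.info("dedup: union %d, intersection with full-cohort panel %d",
                 len(res.union), len(final))
    if "control" in config.replication_designs:
        size = config.control_panel_size or len(panel)
        control = random_control_panel(qc_ids, panel, size, config.seed)
        (out / "control_panel.txt").write_text("".join(f"{s}\n" for s in control))
        cdoses = genetic_dose(qc_matrix, control, mode=config.dose_mode)
        entry = {"size": size}
        if size and cdoses["dose"].nunique() >= 3:
            cfit = fit_dose_response(cdoses, phenotypes, method="individual_ols")
            _write_tsv(pd.DataFrame([{
                "slope": cfit.slope, "slope_se": cfit.slope_se,
                "slope_p": cfit.slope_p, "r_squared": cfit.r_squared,
            }]), out / "control_fit.tsv")
            entry.update(slope=cfit.slope, slope_p=cfit.slope_p)
        stage["control"] = entry
    if "split" in config.replication_designs:
        res = split_half_replication(
            qc_matrix, phenotypes, k=config.k, rule=rule, seed=config.seed,
            dose_mode=config.dose_mode, fit_method=config.fit_method)
        _write_tsv(res.table, out / "split_replication.tsv")
        for row in res.rows:
            (out / f"split_panel1_run{row.experiment_index}.txt").write_text(
                "".join(f"{s}\n" for s in row.panel1))
            (out / f"split_panel2_run{row.experiment_index}.txt").write_text(
                "".join(f"{s}\n" for s in row.panel2))
        stage["split"] = {"k": config.k, "run_seeds": [r.seed for r in res.rows]}

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
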