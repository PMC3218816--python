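"""Readers and writers for the formats the pipeline touches.

Genotypes travel either as VCF (v4.2, GT fields, 1-based positions; REF is
the major and ALT the minor allele, so ALT counts equal minor-allele
dosages) or as a dosage TSV (tab-separated, first column the subject id,
header row of SNP ids, values 0/1/2 with NA for missing).  Phenotype /
assignment tables are plain TSV with a header row.  On reading, dosages
are re-oriented to count the in-sample minor allele; any flip relative to
the file's coded allele is logged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genostats import SnpMeta, compute_maf
from .simulate import GenotypeMatrix

logger = logging.getLogger("gxescan")

__all__ = [
    "AnalysisConfig",
    "load_config",
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "atomic_write_tsv",
]

DEFAULT_Q = {"E_ALONE": 0.5, "E_PLUS_P": 0.5, "DMQ": 0.4, "CAD": 0.5}


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration (flat key-value YAML on disk)."""

    out_dir: str
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    q: dict = field(default_factory=lambda: dict(DEFAULT_Q))
    n_pcs: int = 10
    covariate_cols: list = field(default_factory=lambda: [
        "log_risk_score", "log_bmi", "age",
    ])
    fdr_step_up: bool = False
    n_boot: int = 1000
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    def validate(self, pheno: pd.DataFrame | None = None) -> None:
        for comp, qv in self.q.items():
            if not 0 < qv < 1:
                raise ValueError(f"q for {comp} must lie in (0, 1), got {qv}")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be nonnegative")
        if pheno is not None:
            missing = [c for c in self.covariate_cols if c not in pheno.columns]
            if missing:
                raise ValueError(f"covariate columns not in phenotype table: {missing}")


def load_config(path: str) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# dosage TSV


def write_dosage_tsv(geno: GenotypeMatrix, path: str) -> None:
    df = geno.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dosages = df.to_numpy(dtype=float)
    snps = []
    for j, sid in enumerate(df.columns):
        res = compute_maf(dosages[:, j])
        if res.flipped:
            logger.info("dosage column %s re-oriented to the minor allele", sid)
        dosages[:, j] = res.genotype
        snps.append(SnpMeta(snp_id=str(sid), chromosome="NA", position=j + 1,
                            minor_allele=res.minor_allele,
                            major_allele=res.major_allele, maf=res.maf))
    return GenotypeMatrix(dosages=dosages, snps=snps,
                          sample_ids=df.index.to_numpy())


# ---------------------------------------------------------------------------
# VCF


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Plain-text VCF v4.2; REF = major allele, ALT = minor allele."""
    samples = [str(s) for s in geno.sample_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in enumerate(geno.snps):
            col = geno.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[v] for v in col
            )
            fh.write(f"{snp.chromosome}\t{snp.position}\t{snp.snp_id}\t"
                     f"{snp.major_allele}\t{snp.minor_allele}\t.\tPASS\t.\tGT\t"
                     f"{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read GT dosages with cyvcf2; ALT counts, re-oriented to the minor allele."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.asarray(vcf.samples)
    cols, snps = [], []
    for i, var in enumerate(vcf):
        gts = np.asarray(var.genotypes, dtype=object)
        a1 = np.array([g[0] for g in gts], dtype=float)
        a2 = np.array([g[1] for g in gts], dtype=float)
        dose = a1 + a2  # "0/1" and "1/0" both count one ALT copy
        dose[(a1 < 0) | (a2 < 0)] = np.nan
        alt = var.ALT[0] if var.ALT else "N"
        try:
            res = compute_maf(dose, coded_allele=alt, other_allele=var.REF)
        except ValueError as err:
            raise ValueError(f"malformed VCF record at line {i + 1}: {err}") from err
        if res.flipped:
            logger.info("VCF ALT allele of %s is the in-sample major allele; "
                        "dosages flipped to minor-allele counts", var.ID)
        cols.append(res.genotype)
        snps.append(SnpMeta(
            snp_id=var.ID or f"{var.CHROM}:{var.POS}", chromosome=str(var.CHROM),
            position=int(var.POS), minor_allele=res.minor_allele,
            major_allele=res.major_allele, maf=res.maf,
        ))
    if not snps:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(dosages=np.column_stack(cols), snps=snps,
                          sample_ids=samples)


def read_genotypes(path: str, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format (``vcf`` or ``tsv``; inferred from the extension)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith(".vcf") else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# phenotype table and generic TSV output


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def atomic_write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Write to a temp file in the target directory, then rename."""
    tmp = f"{path}.tmp"
    df.to_csv(tmp, sep="\t", na_rep="NA", index=index)
    os.replace(tmp, path)
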