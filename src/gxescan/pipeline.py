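"""End-to-end pipeline: simulate/load -> genotype stats -> joint test ->
ranking -> interaction profiles -> discrimination.

Every stage writes a self-describing TSV (header row) atomically; a stage
failure leaves the partial output under a ``.partial`` suffix and raises.
Rerunning with the same configuration is bit-identical because every
stochastic stage draws from the configured seed.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import discrimination, fdr, genostats, interaction, jointtest
from .io import AnalysisConfig, atomic_write_tsv, read_genotypes, read_phenotypes
from .simulate import (SimulationConfig, case_control_frame, select_matched_case_control,
                       simulate_cohort)

logger = logging.getLogger("gxescan")

__all__ = ["run_pipeline"]


def _prepare_inputs(config: AnalysisConfig):
    """Load genotype + phenotype inputs, or simulate them."""
    if config.genotypes_path and config.phenotypes_path:
        geno = read_genotypes(config.genotypes_path)
        pheno = read_phenotypes(config.phenotypes_path)
        ids = set(map(str, geno.sample_ids))
        missing = [s for s in map(str, pheno.index) if s not in ids]
        if missing:
            raise ValueError(f"phenotype subjects absent from genotypes: {missing[:5]}")
        order = [list(map(str, geno.sample_ids)).index(str(s)) for s in pheno.index]
        geno.dosages = geno.dosages[order]
        geno.sample_ids = np.asarray(pheno.index)
        return pheno, geno
    sim = SimulationConfig(seed=config.seed, **config.simulate)
    logger.info("simulating cohort: n=%d, snps=%d, seed=%d",
                sim.n_subjects, sim.n_snps, sim.seed)
    cohort, geno = simulate_cohort(sim)
    pairs, unmatched = select_matched_case_control(cohort)
    logger.info("matched %d case-control pairs (%d cases unmatched)",
                len(pairs), len(unmatched))
    cc = case_control_frame(cohort, pairs)
    pos = {s: i for i, s in enumerate(geno.sample_ids)}
    keep = [pos[s] for s in cc.index]
    geno.dosages = geno.dosages[keep]
    geno.sample_ids = cc.index.to_numpy()
    cc["active_DMQ"] = cc["active_DM"]
    return cc, geno


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage; returns the paths of the written artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)
    out = {}
    stage = "inputs"
    try:
        pheno, geno = _prepare_inputs(config)
        config.validate(pheno)

        stage = "genostats"
        snp_ids = geno.snp_ids
        maf_tab = pd.DataFrame({
            "snp_id": snp_ids,
            "chromosome": [s.chromosome for s in geno.snps],
            "position": [s.position for s in geno.snps],
            "minor_allele": [s.minor_allele for s in geno.snps],
            "major_allele": [s.major_allele for s in geno.snps],
            "maf": [s.maf for s in geno.snps],
        })
        loci = genostats.bin_adjacent_loci(
            geno.dosages, maf_tab["chromosome"], maf_tab["position"])
        maf_tab["locus"] = loci
        out["snps"] = os.path.join(config.out_dir, "snps.tsv")
        atomic_write_tsv(maf_tab, out["snps"])

        covariate_cols = list(config.covariate_cols)
        if config.n_pcs > 0:
            k = min(config.n_pcs, min(geno.dosages.shape) - 1)
            pcs = genostats.pca_genotypes(geno.dosages, k=k)
            for i in range(k):
                col = f"pc{i + 1}"
                pheno[col] = pcs.eigenvectors[:, i]
                covariate_cols.append(col)
            logger.info("top %d PCs account for %.1f%% of standardized variance",
                        k, 100 * pcs.variance_fraction.sum())

        stage = "jointtest"
        logger.info("joint test scan over %d SNPs (seed %d)", len(snp_ids), config.seed)
        scan = jointtest.joint_test_scan(
            pheno, geno.dosages, snp_ids, q_by_component=config.q,
            covariate_cols=covariate_cols,
        )
        out["jointtest"] = os.path.join(config.out_dir, "jointtest.tsv")
        atomic_write_tsv(scan, out["jointtest"])

        stage = "rank"
        ok = scan["p_combined"].notna()
        ranked = fdr.rank_and_fdr(scan.loc[ok, "p_combined"], n_tests=len(scan),
                                  snp_ids=scan.loc[ok, "snp_id"],
                                  step_up=config.fdr_step_up)
        out["ranked"] = os.path.join(config.out_dir, "ranked.tsv")
        atomic_write_tsv(ranked, out["ranked"])

        stage = "interaction"
        top = ranked["snp_id"].head(2).tolist()
        rows = []
        for sid in top:
            j = snp_ids.index(sid)
            g = geno.dosages[:, j]
            for comp in jointtest.CASE_ONLY_COMPONENTS:
                sel = (pheno["case"].astype(bool)
                       & pheno[f"in_{comp}"].fillna(False).astype(bool)
                       & ~np.isnan(g))
                if sel.sum() == 0:
                    continue
                res = interaction.genotype_stratified_or(
                    genotype=g[sel.to_numpy()],
                    assignment=pheno.loc[sel, f"active_{comp}"].to_numpy(),
                    q=config.q[comp], component=comp, snp_id=sid,
                )
                rows.append(res.to_frame())
        inter = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["component", "snp_id", "genotype"]))
        out["interaction"] = os.path.join(config.out_dir, "interaction.tsv")
        atomic_write_tsv(inter, out["interaction"])

        stage = "auc"
        assignment_cols = [f"active_{c}" for c in jointtest.CASE_ONLY_COMPONENTS]
        data = pheno.copy()
        for sid in top:
            data[sid] = geno.dosages[:, snp_ids.index(sid)]
        disc = discrimination.bootstrap_auc_test(
            data, snp_cols=top, assignment_cols=assignment_cols,
            confounder_cols=config.covariate_cols,
            n_boot=config.n_boot, seed=config.seed,
        )
        logger.info("bootstrap AUC test: seed %d, n_boot %d", config.seed, config.n_boot)
        auc_tab = pd.DataFrame([
            {"model_label": disc.reference_label, "auc": disc.auc_reference,
             "ci_lo": disc.ci95_reference[0], "ci_hi": disc.ci95_reference[1],
             "delta_auc": 0.0, "bootstrap_p": np.nan},
            {"model_label": disc.model_label, "auc": disc.auc,
             "ci_lo": disc.ci95[0], "ci_hi": disc.ci95[1],
             "delta_auc": disc.delta_auc_vs_reference,
             "bootstrap_p": disc.bootstrap_p},
        ])
        out["auc"] = os.path.join(config.out_dir, "auc.tsv")
        atomic_write_tsv(auc_tab, out["auc"])
    except Exception:
        # keep whatever was mid-write under a .partial suffix
        tmp = os.path.join(config.out_dir, f"{stage}.tsv.tmp")
        if os.path.exists(tmp):
            os.replace(tmp, os.path.join(config.out_dir, f"{stage}.tsv.partial"))
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return out
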