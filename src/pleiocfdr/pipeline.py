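"""End-to-end driver: QC → split → PCA → GWAS → conditional Q-Q → cFDR →
clumping → loci report.

The driver mirrors the split-sample design: the conditioning trait (age
at menarche) is analyzed on half 1 and every metabolic trait on half 2,
so the two GWASs share no samples.  Every stage's output is persisted
under the configured output directory and a run log records the seed,
package version and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .assoc import genotype_pca, run_gwas
from .cfdr import CFDRResult, CombinedCFDR, combine_traits, empirical_cfdr
from .clump import Clump, GenotypeLD, build_loci_table, greedy_clump
from .config import PipelineConfig
from .enrichment import QQCurves, conditional_qq
from .io import (read_dosage_tsv, read_phenotypes, read_vcf,
                 write_loci_table, write_summary_stats)
from .qc import balance_check, sample_qc, snp_qc, split_cohort
from .synthdata import simulate_genotypes, simulate_phenotypes

logger = logging.getLogger("pleiocfdr")


@dataclass
class PipelineResult:
    """Outputs of one full run."""

    loci: pd.DataFrame
    clumps: List[Clump]
    combined: CombinedCFDR
    cfdr_results: Dict[str, CFDRResult]
    qq_curves: Dict[str, QQCurves]
    sumstats: Dict[str, pd.DataFrame]
    balance: pd.DataFrame
    counts: Dict[str, int] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.genotype_path is None:
        sim = config.simulation
        G = simulate_genotypes(sim)
        phenos = simulate_phenotypes(G, sim).data
        return G, phenos
    path = config.genotype_path
    G = read_vcf(path) if path.endswith(".vcf") else read_dosage_tsv(path)
    if config.phenotype_path is None:
        raise ValueError("phenotype_path required with genotype_path")
    phenos = read_phenotypes(config.phenotype_path)
    phenos = phenos.loc[G.sample_ids]
    return G, phenos


def manhattan_data(combined: CombinedCFDR,
                   snp_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP plot table: chromosome, position, −log10 cFDR, trait."""
    if combined.per_trait.empty:
        raise ValueError("no cFDR results to plot")
    meta = snp_meta.set_index("id")[["chrom", "pos"]]
    df = combined.per_trait.join(meta, on="id")
    df["neglog10_cfdr"] = -np.log10(df["cfdr"])
    return df[["chrom", "pos", "id", "trait2", "cfdr",
               "neglog10_cfdr"]].reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for stages.

    Any stage failure propagates with the stage named in the log.  The
    returned bundle carries every intermediate table; the same tables are
    written as TSVs under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, int] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    stage("load")
    G, phenos = _load_inputs(config)
    counts["samples_in"] = G.n_samples
    counts["snps_in"] = G.n_snps

    stage("sample_qc")
    s_rep = sample_qc(G, phenos, config.qc)
    G = G.subset(sample_mask=s_rep.mask)
    phenos = phenos.loc[s_rep.mask]
    counts["samples_qc"] = G.n_samples

    stage("snp_qc")
    v_rep = snp_qc(G, config.qc)
    G = G.subset(snp_mask=v_rep.mask)
    counts["snps_qc"] = G.n_snps

    stage("split")
    ids1, ids2 = split_cohort(G.sample_ids, config.seed)
    in1 = np.isin(G.sample_ids, ids1)
    G1, G2 = G.subset(sample_mask=in1), G.subset(sample_mask=~in1)
    ph1, ph2 = phenos.loc[in1], phenos.loc[~in1]
    counts["half1"], counts["half2"] = G1.n_samples, G2.n_samples

    stage("balance")
    balance = balance_check(ph1, ph2,
                            ["age", "bmi", "bfp", "education", "t2dm"])

    stage("pca")
    k = min(config.pca_k, G1.n_samples - 1, G2.n_samples - 1,
            max(G.n_snps // config.pca_snp_step, 1))
    pcs1 = genotype_pca(G1, k, snp_step=config.pca_snp_step)
    pcs2 = genotype_pca(G2, k, snp_step=config.pca_snp_step)

    stage("gwas")
    sumstats: Dict[str, pd.DataFrame] = {}
    sumstats["aam"] = run_gwas(G1, ph1, "aam", pcs=pcs1, half=1)
    for trait in config.trait2_names:
        sumstats[trait] = run_gwas(G2, ph2, trait, pcs=pcs2, half=2)
    for trait, ss in sumstats.items():
        write_summary_stats(ss, str(out / f"sumstats_{trait}.tsv"))
    counts["snps_tested"] = len(sumstats["aam"])

    p1 = sumstats["aam"]["p"].to_numpy()
    ok1 = np.isfinite(p1)

    stage("conditional_qq")
    qq_curves: Dict[str, QQCurves] = {}
    for trait in config.trait2_names:
        p2 = sumstats[trait]["p"].to_numpy()
        ok = ok1 & np.isfinite(p2)
        qq_curves[trait] = conditional_qq(p2[ok], p1[ok],
                                          config.strata_thresholds)

    stage("cfdr")
    cfdr_results: Dict[str, CFDRResult] = {}
    ids = sumstats["aam"]["id"].to_numpy()
    ok_all = ok1.copy()
    for trait in config.trait2_names:
        ok_all &= np.isfinite(sumstats[trait]["p"].to_numpy())
    for trait in config.trait2_names:
        p2 = sumstats[trait]["p"].to_numpy()
        cfdr_results[trait] = empirical_cfdr(
            p2[ok_all], p1[ok_all], ids=ids[ok_all], trait2=trait,
            alpha=config.alpha)
        cfdr_results[trait].table.to_csv(
            out / f"cfdr_{trait}.tsv", sep="\t", index=False)
    counts["snps_cfdr"] = int(ok_all.sum())

    stage("combine")
    combined = combine_traits(cfdr_results.values(), alpha=config.alpha)

    stage("clump")
    sig = combined.summary[combined.summary["significant"]]
    meta = G.snp_meta.set_index("id")
    snps = pd.DataFrame({"id": sig["id"],
                         "chrom": meta.loc[sig["id"], "chrom"].to_numpy(),
                         "pos": meta.loc[sig["id"], "pos"].to_numpy(),
                         "score": sig["min_cfdr"].to_numpy()})
    clumps = greedy_clump(snps, GenotypeLD(G2), config.clump_window_bp,
                          config.clump_r2_min)
    counts["significant_snps"] = len(sig)
    counts["loci"] = len(clumps)

    stage("loci_table")
    annotations = None
    if config.annotation_path:
        ann = pd.read_csv(config.annotation_path, sep="\t")
        annotations = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    loci = build_loci_table(clumps, combined.per_trait, annotations,
                            config.alpha)
    write_loci_table(loci, str(out / "loci.tsv"),
                     header_comment=f"pleiocfdr {__version__} "
                     f"seed={config.seed}")

    if config.make_figures:
        stage("figures")
        from .plots import manhattan_figure, qq_figure
        qq_figure(qq_curves, str(out / "conditional_qq.png"))
        mh = manhattan_data(combined, G.snp_meta)
        mh.to_csv(out / "manhattan.tsv", sep="\t", index=False)
        manhattan_figure(mh, str(out / "manhattan.png"), config.alpha)

    with open(out / "run_log.json", "w") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "counts": counts}, fh, indent=2)
    logger.info("done: %s", counts)
    return PipelineResult(loci=loci, clumps=clumps, combined=combined,
                          cfdr_results=cfdr_results, qq_curves=qq_curves,
                          sumstats=sumstats, balance=balance,
                          counts=counts)
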