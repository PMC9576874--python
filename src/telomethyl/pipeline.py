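"""End-to-end orchestration: QC chain then the four analysis steps."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_qc, io, mediation, methylation_qc, scans
from .config import AnalysisConfig
from .datamodel import CELL_TYPES, CovariateTable, StudyDataset
from .methylation_qc import CellReferenceMatrix


@dataclass
class PipelineResult:
    dataset: StudyDataset                  # post-QC, estimated cell proportions
    genotype_report: genotype_qc.GenotypeQCReport
    methylation_report: methylation_qc.MethylationQCReport
    association_dominant: pd.DataFrame
    association_additive: pd.DataFrame
    mqtl: scans.MQTLScan
    mediation_candidates: pd.DataFrame
    mediation_results: pd.DataFrame
    interaction: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.genotype_report.to_frame().to_csv(
            d / "genotype_qc_report.tsv", sep="\t", index=False)
        self.association_dominant.to_csv(
            d / "association_dominant.tsv", sep="\t", index=False)
        self.association_additive.to_csv(
            d / "association_additive.tsv", sep="\t", index=False)
        self.mqtl.results.to_csv(d / "mqtl_results.tsv", sep="\t", index=False)
        self.mqtl.significant_pairs.to_csv(
            d / "mqtl_significant_pairs.tsv", sep="\t", index=False)
        self.mediation_candidates.to_csv(
            d / "mediation_candidates.tsv", sep="\t", index=False)
        self.mediation_results.to_csv(
            d / "mediation_results.tsv", sep="\t", index=False)
        self.interaction.to_csv(d / "interaction_results.tsv", sep="\t",
                                index=False)


def run_pipeline(dataset: StudyDataset,
                 detection_p: pd.DataFrame,
                 batch: pd.Series | None,
                 position: pd.Series | None,
                 reference: CellReferenceMatrix,
                 cfg: AnalysisConfig | None = None) -> PipelineResult:
    """QC both data types, align samples, run steps 1-4."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(cfg.seed)

    snps, geno_samples, geno_report = genotype_qc.run_genotype_qc(
        dataset.snps, dataset.sample_ids, rng,
        cfg.snp_call_rate_min, cfg.sample_call_rate_min_geno,
        cfg.maf_min, cfg.hwe_p_min)

    mmat = dataset.mvalue_matrix()
    clean_m, cell_props, meth_report = methylation_qc.run_methylation_qc(
        mmat, detection_p,
        batch if batch is not None else np.zeros(dataset.n_samples, dtype=int),
        position, reference,
        positions={c.id: c.position for c in dataset.cpgs},
        probe_call_rate_min=cfg.probe_call_rate_min,
        sample_call_rate_min=cfg.sample_call_rate_min_meth,
        detection_p_max=cfg.detection_p_max,
        knn_k=cfg.knn_k, iqr_factor=cfg.iqr_factor)

    kept = [s for s in dataset.sample_ids
            if s in geno_samples and s in clean_m.columns]
    geno_idx = [geno_samples.index(s) for s in kept]
    from .datamodel import CpGRecord, PhenotypeVector, SNPRecord
    snps = [SNPRecord(s.id, s.position, s.major_allele, s.minor_allele,
                      s.dosage[geno_idx], SNPRecord.observed_maf(s.dosage[geno_idx]))
            for s in snps]
    clean_m = clean_m[kept]
    cpg_pos = {c.id: c.position for c in dataset.cpgs}
    cpgs = [CpGRecord(pid, cpg_pos[pid], clean_m.loc[pid].to_numpy())
            for pid in clean_m.index]
    full_idx = [dataset.sample_ids.index(s) for s in kept]
    cov_df = dataset.covariates.data.iloc[full_idx].copy()
    for ct in CELL_TYPES:  # replace generative proportions by estimates
        cov_df[ct] = cell_props.loc[kept, ct].to_numpy()
    pheno = PhenotypeVector(dataset.phenotype.tl[full_idx])
    ds = StudyDataset(snps, cpgs, CovariateTable(cov_df), pheno, kept)

    assoc_dom = scans.scan_tl_snp(ds, "dominant", cfg.alpha)
    assoc_add = scans.scan_tl_snp(ds, "additive", cfg.alpha)
    mqtl = scans.scan_mqtl(ds, cfg.cis_window_bp, cfg.alpha,
                           require_both_codings=cfg.mqtl_both_codings)
    candidates = mediation.select_candidates(mqtl, ds, cfg.alpha)
    med_results = mediation.mediate_candidates(ds, candidates,
                                               n_boot=cfg.n_boot,
                                               seed=cfg.seed)
    interaction = scans.scan_interaction(ds, mqtl.significant_pairs,
                                         cfg.cis_window_bp, cfg.alpha,
                                         cfg.n_snp_main_tests)
    return PipelineResult(ds, geno_report, meth_report, assoc_dom, assoc_add,
                          mqtl, candidates, med_results, interaction)


def load_bundle(directory: str | Path):
    """Read a simulated study bundle (dataset + QC side files)."""
    d = Path(directory)
    ds = io.read_dataset(d)
    detection = io.read_matrix(d / "detection_p.tsv")
    tech_path = d / "technical.tsv"
    batch = position = None
    if tech_path.exists():
        tech = pd.read_csv(tech_path, sep="\t", index_col="sample_id")
        batch = tech["batch"]
        position = tech["position"]
    ref = None
    ref_path = d / "cell_reference.tsv"
    if ref_path.exists():
        ref = CellReferenceMatrix(io.read_matrix(ref_path))
    return ds, detection, batch, position, ref
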