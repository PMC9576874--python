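"""Simulation experiments that quantify what the pipeline recovers.

The cohort's individual-level data are not deposited, so the published
effect sizes are used as generative truth and each experiment measures how
the corresponding analysis step recovers them (or how its error control
behaves under the null).  These functions back both the test suite and
``scripts/acceptance.py``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mediation, scans, simulate
from .datamodel import (
    CpGRecord,
    GenomicPosition,
    PhenotypeVector,
    SNPRecord,
    StudyDataset,
)

#: Published fitted coefficients of the interaction model (T/S-ratio scale).
INTERACTION_TRUTH = {"beta12": -0.330, "beta_snp": 1.186, "beta_cpg": 0.263}


def _two_feature_dataset(dosage: np.ndarray, m: np.ndarray, tl: np.ndarray
                         ) -> StudyDataset:
    """A covariate-free dataset with one SNP and one cis CpG."""
    n = len(tl)
    ids = [f"S{i}" for i in range(n)]
    snp = SNPRecord.from_dosages("rs1", GenomicPosition("chr1", 1_000_000),
                                 "A", "G", dosage)
    cpg = CpGRecord("cg00000001", GenomicPosition("chr1", 1_015_000), m)
    return StudyDataset([snp], [cpg], None, PhenotypeVector(tl), ids)


def _interaction_cfg(n: int, maf: float, seed: int) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_samples=n,
        snp_spec=[simulate.SNPSpec("rs1", "chr1", 1_000_000, maf)],
        cpg_spec=[simulate.CpGSpec("cg00000001", "chr1", 1_015_000, 0.0)],
        interaction_terms=[("rs1", "cg00000001", INTERACTION_TRUTH["beta12"])],
        snp_effects_additive=[("rs1", INTERACTION_TRUTH["beta_snp"])],
        cpg_effects=[("cg00000001", INTERACTION_TRUTH["beta_cpg"])],
        cell_model=False, cpg_noise_sd=1.0,
        missing_rate_geno=0.0, missing_rate_meth=0.0, detection_fail_rate=0.0,
        tl_mean=1.03, tl_sd=0.20, seed=seed,
    )


@dataclass
class RecoveryResult:
    mean_beta12: float
    mean_beta_snp: float
    mc_se_beta12: float
    mc_se_beta_snp: float
    n_replicates: int
    n_samples: int


def interaction_recovery(seed: int = 1, n_replicates: int = 200,
                         n_samples: int = 5_000, maf: float = 0.3
                         ) -> RecoveryResult:
    """Recover the interaction-model coefficients from synthetic cohorts.

    Each replicate simulates one SNP (additive, given MAF), one standard
    normal CpG and a telomere phenotype generated from the interaction
    structural model with the published coefficients, covariates off;
    the interaction scan is then run and its estimates collected.
    """
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    b12, b1 = np.empty(n_replicates), np.empty(n_replicates)
    for r, s in enumerate(rep_seeds):
        cfg = _interaction_cfg(n_samples, maf, int(s))
        rng = np.random.default_rng(cfg.seed)
        _, latent_d = simulate.simulate_genotypes(cfg, rng)
        meth = simulate.simulate_methylation(cfg, latent_d, rng)
        pheno, _ = simulate.simulate_phenotype(cfg, latent_d,
                                               meth["latent_mvalues"], None, rng)
        ds = _two_feature_dataset(latent_d.iloc[0].to_numpy(),
                                  meth["latent_mvalues"].iloc[0].to_numpy(),
                                  pheno.tl)
        res = scans.scan_interaction(ds, None)
        b12[r] = res["beta12"].iloc[0]
        b1[r] = res["beta_snp"].iloc[0]
    return RecoveryResult(float(b12.mean()), float(b1.mean()),
                          float(b12.std(ddof=1) / np.sqrt(n_replicates)),
                          float(b1.std(ddof=1) / np.sqrt(n_replicates)),
                          n_replicates, n_samples)


def bonferroni_fwer(seed: int = 1, n_runs: int = 400, n_pairs: int = 2_000,
                    n_samples: int = 200, alpha: float = 0.05
                    ) -> dict[str, float]:
    """Family-wise error of the Bonferroni-controlled mQTL scan under a
    global null (no mQTL effects), measured per coding on additive flags."""
    master = np.random.default_rng(seed)
    hits = 0
    snp_pos = 1_000_000
    positions = [snp_pos - 400_000 + (800_000 * j) // max(n_pairs - 1, 1)
                 for j in range(n_pairs)]
    for _ in range(n_runs):
        d = master.binomial(2, 0.3, size=n_samples).astype(float)
        M = master.normal(size=(n_pairs, n_samples))
        snp = SNPRecord.from_dosages("rs1", GenomicPosition("chr1", snp_pos),
                                     "A", "G", d)
        cpgs = [CpGRecord(f"cg{j:08d}", GenomicPosition("chr1", positions[j]),
                          M[j]) for j in range(n_pairs)]
        ids = [f"S{i}" for i in range(n_samples)]
        ds = StudyDataset([snp], cpgs, None,
                          PhenotypeVector(np.abs(master.normal(1.0, 0.2,
                                                               n_samples))), ids)
        scan = scans.scan_mqtl(ds, alpha=alpha)
        add = scan.results[scan.results["coding"] == "additive"]
        hits += int(add["bonferroni_significant"].any())
    return {"fwer": hits / n_runs, "threshold": alpha / n_pairs,
            "n_runs": n_runs, "n_pairs": n_pairs}


def mediation_coverage(seed: int = 1, n_sims: int = 300, n_samples: int = 500,
                       n_boot: int = 500, a: float = 0.8, b: float = 0.25,
                       c_prime: float = 0.0) -> dict[str, float]:
    """Coverage of the 95% bootstrap-percentile CI for the indirect effect,
    and (with a = 0) the size of the bootstrap IE test."""
    master = np.random.default_rng(seed)
    true_ie = a * b
    covered = 0
    rejected = 0
    for _ in range(n_sims):
        d = master.binomial(2, 0.3, size=n_samples).astype(float)
        dom = (d > 0).astype(float)
        m = a * dom + master.normal(size=n_samples)
        tl = 1.03 + c_prime * dom + b * m + master.normal(0.0, 0.2, n_samples)
        ds = _two_feature_dataset(d, m, tl)
        res = mediation.bootstrap_mediation(ds, "rs1", "cg00000001",
                                            n_boot=n_boot,
                                            seed=int(master.integers(2**31 - 1)))
        lo, hi = res.ci["ie"]
        covered += int(lo <= true_ie <= hi)
        rejected += int(res.boot_p["ie"] < 0.05)
    return {"coverage": covered / n_sims, "rejection_rate": rejected / n_sims,
            "true_ie": true_ie, "n_sims": n_sims}
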