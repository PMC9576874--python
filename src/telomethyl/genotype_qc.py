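"""Genotype quality control.

Filter chain, applied in this fixed order:

1. call-rate filters — SNPs with non-missing fraction < 95% first, then
   samples with non-missing fraction (over retained SNPs) < 90%;
2. imputation of remaining missing dosages by draws from each SNP's
   empirical genotype distribution;
3. MAF / Hardy-Weinberg filters — drop SNPs with MAF < 0.01 or a 1-df
   Pearson HWE chi-square p-value < 0.05 (strict inequalities).

All thresholds are configurable; the defaults are the protocol values.
The module also provides dominant/additive genotype coding and the
pairwise LD r^2 matrix of dosages.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SNPRecord


@dataclass
class GenotypeQCReport:
    snps_dropped_call_rate: list[str] = field(default_factory=list)
    samples_dropped_call_rate: list[str] = field(default_factory=list)
    snps_dropped_maf: list[str] = field(default_factory=list)
    snps_dropped_hwe: list[str] = field(default_factory=list)
    snp_call_rates: dict[str, float] = field(default_factory=dict)
    sample_call_rates: dict[str, float] = field(default_factory=dict)
    maf_table: dict[str, float] = field(default_factory=dict)
    hwe_table: dict[str, tuple[float, float]] = field(default_factory=dict)
    imputed_count: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-SNP summary (call rate, MAF, HWE chi2/p, drop reason)."""
        rows = []
        for sid, cr in self.snp_call_rates.items():
            reason = ""
            if sid in self.snps_dropped_call_rate:
                reason = "call_rate"
            elif sid in self.snps_dropped_maf:
                reason = "maf"
            elif sid in self.snps_dropped_hwe:
                reason = "hwe"
            chi2, p = self.hwe_table.get(sid, (np.nan, np.nan))
            rows.append((sid, cr, self.maf_table.get(sid, np.nan), chi2, p, reason))
        return pd.DataFrame(
            rows, columns=["snp_id", "call_rate", "maf", "hwe_chi2", "hwe_p",
                           "dropped_for"])


class EmptyResultError(ValueError):
    pass


def filter_call_rates(snps: list[SNPRecord], sample_ids: list[str],
                      snp_call_rate_min: float = 0.95,
                      sample_call_rate_min: float = 0.90,
                      report: GenotypeQCReport | None = None,
                      ) -> tuple[list[SNPRecord], list[str], GenotypeQCReport]:
    """Apply SNP-then-sample call-rate filters.

    Returns (retained SNPs restricted to retained samples, retained sample
    IDs, report).  Thresholds are strict: exactly-at-threshold call rates
    are retained.
    """
    report = report or GenotypeQCReport()
    kept = []
    for s in snps:
        cr = float(np.mean(~np.isnan(s.dosage)))
        report.snp_call_rates[s.id] = cr
        if cr < snp_call_rate_min:
            report.snps_dropped_call_rate.append(s.id)
        else:
            kept.append(s)
    if not kept:
        raise EmptyResultError("all SNPs dropped by the call-rate filter")
    dosage = np.vstack([s.dosage for s in kept])  # SNPs x samples
    sample_cr = np.mean(~np.isnan(dosage), axis=0)
    keep_mask = sample_cr >= sample_call_rate_min
    for sid, cr, ok in zip(sample_ids, sample_cr, keep_mask):
        report.sample_call_rates[sid] = float(cr)
        if not ok:
            report.samples_dropped_call_rate.append(sid)
    kept_samples = [sid for sid, ok in zip(sample_ids, keep_mask) if ok]
    if not kept_samples:
        raise EmptyResultError("all samples dropped by the call-rate filter")
    out = []
    for s in kept:
        d = s.dosage[keep_mask]
        out.append(SNPRecord(s.id, s.position, s.major_allele, s.minor_allele,
                             d, SNPRecord.observed_maf(d)))
    return out, kept_samples, report


def impute_genotypes(snps: list[SNPRecord], rng: np.random.Generator,
                     report: GenotypeQCReport | None = None
                     ) -> tuple[list[SNPRecord], GenotypeQCReport]:
    """Fill missing dosages by draws from each SNP's empirical genotype
    distribution (deterministic under a seeded generator)."""
    report = report or GenotypeQCReport()
    out = []
    for s in snps:
        d = s.dosage.copy()
        miss = np.isnan(d)
        if miss.all():
            raise ValueError(f"SNP {s.id} has no observed genotypes")
        if miss.any():
            obs = d[~miss]
            counts = np.array([(obs == g).sum() for g in (0.0, 1.0, 2.0)], dtype=float)
            d[miss] = rng.choice([0.0, 1.0, 2.0], size=int(miss.sum()),
                                 p=counts / counts.sum())
            report.imputed_count += int(miss.sum())
        out.append(SNPRecord(s.id, s.position, s.major_allele, s.minor_allele,
                             d, SNPRecord.observed_maf(d)))
    return out, report


def hwe_test(n_major_hom: int, n_het: int, n_minor_hom: int
             ) -> tuple[float, float]:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts use the observed allele frequency; no continuity
    correction.  Monomorphic input is defined as (chi2=0, p=1).
    """
    n = n_major_hom + n_het + n_minor_hom
    if n <= 0:
        raise ValueError("need at least one genotype")
    p_major = (2 * n_major_hom + n_het) / (2 * n)
    if p_major in (0.0, 1.0):
        return 0.0, 1.0
    q = 1.0 - p_major
    expected = np.array([p_major ** 2, 2 * p_major * q, q ** 2]) * n
    observed = np.array([n_major_hom, n_het, n_minor_hom], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def hwe_test_snp(snp: SNPRecord) -> tuple[float, float]:
    d = snp.dosage
    if np.isnan(d).any():
        raise ValueError(f"SNP {snp.id} has missing dosages; impute first")
    return hwe_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def filter_maf_hwe(snps: list[SNPRecord], maf_min: float = 0.01,
                   hwe_p_min: float = 0.05,
                   report: GenotypeQCReport | None = None
                   ) -> tuple[list[SNPRecord], GenotypeQCReport]:
    """Retain SNPs with MAF >= maf_min AND HWE p >= hwe_p_min."""
    report = report or GenotypeQCReport()
    out = []
    for s in snps:
        maf = SNPRecord.observed_maf(s.dosage)
        chi2, p = hwe_test_snp(s)
        report.maf_table[s.id] = maf
        report.hwe_table[s.id] = (chi2, p)
        if maf < maf_min:
            report.snps_dropped_maf.append(s.id)
        elif p < hwe_p_min:
            report.snps_dropped_hwe.append(s.id)
        else:
            out.append(s)
    return out, report


@dataclass
class CodedGenotype:
    snp_id: str
    coding: str                    # "dominant" or "additive"
    values: np.ndarray
    is_constant: bool = False


def code_genotypes(snp: SNPRecord, coding: str) -> CodedGenotype:
    """Code dosages: dominant = carrier indicator {0,1}, additive = dosage."""
    d = snp.dosage
    if np.isnan(d).any():
        raise ValueError(f"SNP {snp.id} has missing dosages; impute first")
    if coding == "dominant":
        v = (d > 0).astype(float)
    elif coding == "additive":
        v = d.astype(float)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return CodedGenotype(snp.id, coding, v, is_constant=bool(np.ptp(v) == 0))


def ld_r2_matrix(snps: list[SNPRecord]) -> pd.DataFrame:
    """Pairwise squared Pearson correlation (LD r^2) of dosages.

    Constant SNPs get missing rows/columns (their correlation is
    undefined); polymorphic diagonals are exactly 1.
    """
    if len(snps) < 2:
        raise ValueError("need >= 2 SNPs for an LD matrix")
    ids = [s.id for s in snps]
    D = np.vstack([s.dosage for s in snps])
    if np.isnan(D).any():
        raise ValueError("missing dosages; impute first")
    sd = D.std(axis=1)
    poly = sd > 0
    r2 = np.full((len(snps), len(snps)), np.nan)
    if poly.sum() >= 1:
        sub = np.corrcoef(D[poly])
        sub = np.atleast_2d(sub)
        r2[np.ix_(poly, poly)] = sub ** 2
    return pd.DataFrame(r2, index=ids, columns=ids)


def run_genotype_qc(snps: list[SNPRecord], sample_ids: list[str],
                    rng: np.random.Generator,
                    snp_call_rate_min: float = 0.95,
                    sample_call_rate_min: float = 0.90,
                    maf_min: float = 0.01, hwe_p_min: float = 0.05,
                    ) -> tuple[list[SNPRecord], list[str], GenotypeQCReport]:
    """The full chain: call rates -> imputation -> MAF/HWE."""
    report = GenotypeQCReport()
    snps, kept_samples, report = filter_call_rates(
        snps, sample_ids, snp_call_rate_min, sample_call_rate_min, report)
    snps, report = impute_genotypes(snps, rng, report)
    snps, report = filter_maf_hwe(snps, maf_min, hwe_p_min, report)
    if not snps:
        raise EmptyResultError("all SNPs dropped by MAF/HWE filters")
    return snps, kept_samples, report
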