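"""Core domain types shared by every stage of the pipeline.

The study design this package models is a birth cohort in which, per
mother-newborn pair, we observe

* genotypes at a small panel of candidate SNPs (minor-allele dosages),
* cord-blood DNA methylation at CpG probes, expressed as M-values,
* a covariate table (newborn and maternal characteristics plus estimated
  cord-blood cell-type proportions), and
* relative telomere length as a qPCR T/S ratio.

All per-sample containers share one sample ordering; :func:`validate_dataset`
checks that and every other structural invariant, returning a report rather
than raising so callers can surface all problems at once.

Coordinates are 1-based inclusive internally; BED manifests are the only
0-based surface and are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Cord-blood cell types quantified by reference-based deconvolution,
#: in canonical column order.
CELL_TYPES = ("nRBC", "Gran", "Mono", "NK", "Bcell", "CD4T", "CD8T")

PARITY_LEVELS = ("primiparous", "secundiparous", "multiparous")
EDUCATION_LEVELS = ("no_diploma", "high_school", "college_3yr", "university_4yr")
SMOKING_LEVELS = ("never", "former", "current")

#: Covariate-table columns in file order (cell proportions appended).
COVARIATE_COLUMNS = (
    "sex",
    "gestational_age",
    "ethnicity",
    "birth_weight",
    "pregnancy_complications",
    "pre_pregnancy_bmi",
    "parity",
    "education",
    "smoking",
    "paternal_age",
)

NUMERIC_COVARIATES = ("gestational_age", "birth_weight", "pre_pregnancy_bmi", "paternal_age")
BINARY_COVARIATES = ("sex", "ethnicity", "pregnancy_complications")
CATEGORICAL_COVARIATES = {
    "parity": PARITY_LEVELS,
    "education": EDUCATION_LEVELS,
    "smoking": SMOKING_LEVELS,
}


@dataclass(frozen=True)
class GenomicPosition:
    """A 1-based genomic coordinate (``chrom``, ``pos``)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    def __str__(self) -> str:  # e.g. "chr10:103916188"
        return f"{self.chrom}:{self.pos}"


def _as_float_array(values: Sequence[float]) -> np.ndarray:
    return np.asarray(values, dtype=float)


@dataclass
class SNPRecord:
    """A biallelic SNP with per-sample minor-allele dosages.

    ``dosage`` holds minor-allele counts in {0, 1, 2} with ``nan`` for
    missing; ``maf`` is the minor-allele frequency among non-missing
    dosages and is always <= 0.5 after orientation.
    """

    id: str
    position: GenomicPosition
    major_allele: str
    minor_allele: str
    dosage: np.ndarray
    maf: float

    def __post_init__(self) -> None:
        self.dosage = _as_float_array(self.dosage)

    @staticmethod
    def observed_maf(dosage: np.ndarray) -> float:
        """Minor-allele frequency of a dosage vector (nan-aware)."""
        d = np.asarray(dosage, dtype=float)
        obs = d[~np.isnan(d)]
        if obs.size == 0:
            return float("nan")
        return float(obs.sum() / (2 * obs.size))

    @classmethod
    def from_dosages(
        cls,
        id: str,
        position: GenomicPosition,
        allele_a: str,
        allele_b: str,
        dosage_b: Sequence[float],
    ) -> "SNPRecord":
        """Build a record orienting dosages to the minor allele.

        ``dosage_b`` counts copies of ``allele_b``.  If the observed
        frequency of ``allele_b`` exceeds 0.5 the dosages are flipped
        (2 - d) and the allele labels swapped; an exact tie keeps
        ``allele_b`` as the minor allele (deterministic convention).
        """
        d = _as_float_array(dosage_b)
        freq = cls.observed_maf(d)
        if np.isnan(freq) or freq <= 0.5:
            major, minor = allele_a, allele_b
        else:
            major, minor = allele_b, allele_a
            d = 2.0 - d
            freq = 1.0 - freq
        return cls(id=id, position=position, major_allele=major,
                   minor_allele=minor, dosage=d, maf=freq)

    def n_samples(self) -> int:
        return int(self.dosage.size)

    def validate(self) -> list[str]:
        problems = []
        obs = self.dosage[~np.isnan(self.dosage)]
        if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            problems.append(f"SNP {self.id}: dosages outside {{0,1,2,NA}}")
        recomputed = self.observed_maf(self.dosage)
        if not np.isnan(recomputed) and abs(recomputed - self.maf) > 1e-12:
            problems.append(
                f"SNP {self.id}: stored maf {self.maf} != recomputed {recomputed}")
        if not np.isnan(self.maf) and self.maf > 0.5 + 1e-12:
            problems.append(f"SNP {self.id}: maf {self.maf} > 0.5")
        return problems


@dataclass
class CpGRecord:
    """A CpG probe with per-sample M-values (``nan`` for missing)."""

    id: str
    position: GenomicPosition
    mvalues: np.ndarray

    def __post_init__(self) -> None:
        self.mvalues = _as_float_array(self.mvalues)

    def n_samples(self) -> int:
        return int(self.mvalues.size)

    def validate(self) -> list[str]:
        problems = []
        if not self.id.startswith("cg"):
            problems.append(f"CpG {self.id}: probe ID not cg-prefixed")
        vals = self.mvalues[~np.isnan(self.mvalues)]
        if not np.all(np.isfinite(vals)):
            problems.append(f"CpG {self.id}: non-finite M-values")
        return problems


@dataclass
class CovariateTable:
    """Per-sample covariates and 7 cord-blood cell proportions.

    Wraps a :class:`pandas.DataFrame` indexed by sample ID with the
    columns in :data:`COVARIATE_COLUMNS` plus one column per entry of
    :data:`CELL_TYPES`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def cell_proportions(self) -> pd.DataFrame:
        return self.data[list(CELL_TYPES)]

    def validate(self) -> list[str]:
        problems = []
        missing_cols = [c for c in COVARIATE_COLUMNS + CELL_TYPES
                        if c not in self.data.columns]
        if missing_cols:
            problems.append(f"covariates: missing columns {missing_cols}")
            return problems
        for col, levels in CATEGORICAL_COVARIATES.items():
            bad = set(self.data[col].astype(str)) - set(levels)
            if bad:
                problems.append(f"covariates: {col} has undeclared levels {sorted(bad)}")
        for col in BINARY_COVARIATES:
            vals = set(pd.unique(self.data[col]))
            if not vals <= {0, 1, 0.0, 1.0}:
                problems.append(f"covariates: {col} not binary 0/1")
        props = self.cell_proportions.to_numpy(dtype=float)
        if (props < -1e-12).any():
            bad_rows = self.data.index[(props < -1e-12).any(axis=1)].tolist()
            problems.append(f"covariates: negative cell proportions for samples {bad_rows}")
        sums = props.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            for sid, s in zip(self.data.index[off], sums[off]):
                problems.append(
                    f"covariates: cell proportions for sample {sid} sum to {s:.6g}, not 1")
        return problems


@dataclass
class PhenotypeVector:
    """Per-sample telomere length as a qPCR T/S ratio (positive real)."""

    tl: np.ndarray

    def __post_init__(self) -> None:
        self.tl = _as_float_array(self.tl)

    @property
    def n_samples(self) -> int:
        return int(self.tl.size)

    def validate(self) -> list[str]:
        problems = []
        if (self.tl <= 0).any():
            idx = np.nonzero(self.tl <= 0)[0].tolist()
            problems.append(f"phenotype: non-positive T/S ratio at sample indices {idx}")
        return problems


@dataclass
class StudyDataset:
    """Aligned per-sample bundle of genotypes, methylation, covariates, phenotype."""

    snps: list[SNPRecord]
    cpgs: list[CpGRecord]
    covariates: CovariateTable | None
    phenotype: PhenotypeVector
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snp(self, snp_id: str) -> SNPRecord:
        for s in self.snps:
            if s.id == snp_id:
                return s
        raise KeyError(f"no SNP {snp_id!r} in dataset")

    def cpg(self, cpg_id: str) -> CpGRecord:
        for c in self.cpgs:
            if c.id == cpg_id:
                return c
        raise KeyError(f"no CpG {cpg_id!r} in dataset")

    def dosage_matrix(self) -> pd.DataFrame:
        """SNPs x samples dosage matrix."""
        return pd.DataFrame(
            np.vstack([s.dosage for s in self.snps]) if self.snps else
            np.empty((0, self.n_samples)),
            index=[s.id for s in self.snps], columns=self.sample_ids)

    def mvalue_matrix(self) -> pd.DataFrame:
        """Probes x samples M-value matrix."""
        return pd.DataFrame(
            np.vstack([c.mvalues for c in self.cpgs]) if self.cpgs else
            np.empty((0, self.n_samples)),
            index=[c.id for c in self.cpgs], columns=self.sample_ids)

    def subset_samples(self, keep: Sequence[str]) -> "StudyDataset":
        """Return a dataset restricted (and reordered) to ``keep`` sample IDs."""
        idx = [self.sample_ids.index(s) for s in keep]
        snps = [
            SNPRecord(s.id, s.position, s.major_allele, s.minor_allele,
                      s.dosage[idx], SNPRecord.observed_maf(s.dosage[idx]))
            for s in self.snps
        ]
        cpgs = [CpGRecord(c.id, c.position, c.mvalues[idx]) for c in self.cpgs]
        cov = (CovariateTable(self.covariates.data.iloc[idx])
               if self.covariates is not None else None)
        pheno = PhenotypeVector(self.phenotype.tl[idx])
        return StudyDataset(snps, cpgs, cov, pheno, list(keep))


def validate_dataset(ds: StudyDataset) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the dataset is valid.  Violations name the
    offending component (and sample where applicable) so a caller can
    report them all at once.
    """
    problems: list[str] = []
    n = ds.n_samples
    if len(set(ds.sample_ids)) != n:
        problems.append("sample_ids: duplicate sample IDs")

    snp_ids = [s.id for s in ds.snps]
    if len(set(snp_ids)) != len(snp_ids):
        problems.append("snps: duplicate SNP IDs")
    cpg_ids = [c.id for c in ds.cpgs]
    if len(set(cpg_ids)) != len(cpg_ids):
        problems.append("cpgs: duplicate CpG IDs")

    for s in ds.snps:
        if s.n_samples() != n:
            problems.append(f"snps: SNP {s.id} has {s.n_samples()} samples, expected {n}")
        problems.extend(s.validate())
    for c in ds.cpgs:
        if c.n_samples() != n:
            problems.append(f"cpgs: CpG {c.id} has {c.n_samples()} samples, expected {n}")
        problems.extend(c.validate())

    if ds.covariates is not None:
        if ds.covariates.n_samples != n:
            problems.append(
                f"covariates: {ds.covariates.n_samples} samples, expected {n}")
        problems.extend(ds.covariates.validate())

    if ds.phenotype.n_samples != n:
        problems.append(
            f"phenotype: {ds.phenotype.n_samples} samples, expected {n}")
    problems.extend(ds.phenotype.validate())
    return problems
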