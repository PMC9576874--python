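"""Readers and writers for the pipeline's tabular formats.

One TSV dialect throughout: tab-separated, header row, missing token "NA",
floats written with 12 significant digits so write->read round-trips are
exact at 1e-12.  Genotypes can additionally be read from a minimal VCF
(plain-text, biallelic, GT field only) and written to one.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CELL_TYPES,
    COVARIATE_COLUMNS,
    CovariateTable,
    CpGRecord,
    GenomicPosition,
    PhenotypeVector,
    SNPRecord,
    StudyDataset,
)

MISSING = "NA"
_FLOAT_FMT = "{:.17g}"  # shortest-exact round-trip for doubles


class ParseError(ValueError):
    """Malformed input file; message names the offending line/record."""


def _fmt(v: float) -> str:
    if np.isnan(v):
        return MISSING
    return _FLOAT_FMT.format(v)


def _parse_float(token: str, where: str) -> float:
    if token == MISSING or token == "":
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"non-numeric value {token!r} at {where}") from None


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, format: str = "tsv") -> list[SNPRecord]:
    """Read SNP records from a genotype TSV or a minimal VCF.

    Dosages are oriented to minor-allele counts on read and ``maf`` is
    populated from the non-missing dosages.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str | Path) -> list[SNPRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[:5] != ["id", "chrom", "pos", "major", "minor"]:
        raise ParseError(f"{path} line 1: bad genotype header {header[:5]}")
    samples = header[5:]
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        tok = line.split("\t")
        if len(tok) != 5 + len(samples):
            raise ParseError(
                f"{path} line {ln}: expected {5 + len(samples)} fields, got {len(tok)}")
        dosages = [_parse_float(t, f"{path} line {ln}") for t in tok[5:]]
        for d in dosages:
            if not np.isnan(d) and d not in (0.0, 1.0, 2.0):
                raise ParseError(f"{path} line {ln}: dosage {d} not in {{0,1,2,NA}}")
        pos = GenomicPosition(tok[1], int(tok[2]))
        records.append(SNPRecord.from_dosages(tok[0], pos, tok[3], tok[4], dosages))
    return records


def write_genotypes(path: str | Path, snps: Iterable[SNPRecord],
                    sample_ids: list[str]) -> None:
    lines = ["\t".join(["id", "chrom", "pos", "major", "minor"] + sample_ids)]
    for s in snps:
        row = [s.id, s.position.chrom, str(s.position.pos),
               s.major_allele, s.minor_allele]
        row += [MISSING if np.isnan(d) else str(int(d)) for d in s.dosage]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_genotypes_vcf(path: str | Path) -> list[SNPRecord]:
    """Minimal VCF 4.x reader: plain text, biallelic records, GT field."""
    records = []
    samples: list[str] | None = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##") or not line:
            continue
        if line.startswith("#CHROM"):
            cols = line.lstrip("#").split("\t")
            if cols[:9] != ["CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                            "FILTER", "INFO", "FORMAT"]:
                raise ParseError(f"{path} line {ln}: unexpected VCF column header")
            samples = cols[9:]
            continue
        if samples is None:
            raise ParseError(f"{path} line {ln}: data before #CHROM header")
        tok = line.split("\t")
        if len(tok) != 9 + len(samples):
            raise ParseError(f"{path} line {ln}: field count mismatch")
        chrom, pos, vid, ref, alt = tok[0], tok[1], tok[2], tok[3], tok[4]
        if "," in alt:
            raise ParseError(f"{path}: multi-allelic record {vid!r} rejected")
        fmt_keys = tok[8].split(":")
        if "GT" not in fmt_keys:
            raise ParseError(f"{path} line {ln}: record {vid!r} has no GT field")
        gt_i = fmt_keys.index("GT")
        dosages = []
        for stok in tok[9:]:
            gt = stok.split(":")[gt_i]
            if gt in (".", "./.", ".|."):
                dosages.append(float("nan"))
                continue
            alleles = gt.replace("|", "/").split("/")
            if len(alleles) != 2 or not set(alleles) <= {"0", "1"}:
                raise ParseError(f"{path} line {ln}: bad GT {gt!r} for {vid!r}")
            dosages.append(float(alleles.count("1")))
        position = GenomicPosition(chrom, int(pos))
        records.append(SNPRecord.from_dosages(vid, position, ref, alt, dosages))
    if samples is None:
        raise ParseError(f"{path}: no #CHROM header found")
    return records


def write_vcf(path: str | Path, snps: Iterable[SNPRecord],
              sample_ids: list[str]) -> None:
    """Write genotypes as a minimal VCF with REF=major, ALT=minor."""
    gt_by_dosage = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2",
             "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">",
             "#" + "\t".join(["CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                              "FILTER", "INFO", "FORMAT"] + sample_ids)]
    for s in snps:
        gts = ["./." if np.isnan(d) else gt_by_dosage[d] for d in s.dosage]
        lines.append("\t".join(
            [s.position.chrom, str(s.position.pos), s.id, s.major_allele,
             s.minor_allele, ".", "PASS", ".", "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# methylation matrices (probes x samples)

def read_methylation(path: str | Path) -> list[CpGRecord]:
    """Read a probes-x-samples M-value TSV into CpG records (no positions).

    Positions are attached separately from a manifest via
    :func:`attach_positions`.
    """
    m = read_matrix(path)
    placeholder = GenomicPosition("chrUn", 1)
    return [CpGRecord(pid, placeholder, m.loc[pid].to_numpy(dtype=float))
            for pid in m.index]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-x-sample numeric TSV (first column = feature ID)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split("\t")
    samples = header[1:]
    ids, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        tok = line.split("\t")
        if len(tok) != 1 + len(samples):
            raise ParseError(
                f"{path} line {ln}: probe {tok[0]!r} has {len(tok) - 1} values, "
                f"expected {len(samples)}")
        if tok[0] in ids:
            raise ParseError(f"{path} line {ln}: duplicate probe ID {tok[0]!r}")
        ids.append(tok[0])
        rows.append([_parse_float(t, f"{path} line {ln} probe {tok[0]}")
                     for t in tok[1:]])
    return pd.DataFrame(np.asarray(rows, dtype=float) if rows else
                        np.empty((0, len(samples))), index=ids, columns=samples)


def write_matrix(path: str | Path, matrix: pd.DataFrame,
                 index_name: str = "probe_id") -> None:
    lines = ["\t".join([index_name] + [str(c) for c in matrix.columns])]
    values = matrix.to_numpy(dtype=float)
    for pid, row in zip(matrix.index, values):
        lines.append("\t".join([str(pid)] + [_fmt(v) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def attach_positions(cpgs: list[CpGRecord],
                     manifest: Mapping[str, GenomicPosition]) -> list[CpGRecord]:
    out = []
    for c in cpgs:
        if c.id not in manifest:
            raise KeyError(f"CpG {c.id} missing from manifest")
        out.append(CpGRecord(c.id, manifest[c.id], c.mvalues))
    return out


# ---------------------------------------------------------------------------
# manifests (BED-like, half-open 0-based -> 1-based internal)

def read_manifest(path: str | Path) -> dict[str, GenomicPosition]:
    """Read a BED-like manifest of single-base features.

    BED rows are ``chrom  start  end  name`` with 0-based half-open
    coordinates; the internal 1-based position is ``start + 1`` and
    ``end`` must equal ``start + 1``.
    """
    out: dict[str, GenomicPosition] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        tok = line.split("\t")
        if len(tok) < 4:
            raise ParseError(f"{path} line {ln}: expected 4 BED fields")
        chrom, start, end, name = tok[0], int(tok[1]), int(tok[2]), tok[3]
        if end != start + 1:
            raise ParseError(
                f"{path} line {ln}: feature {name!r} spans {end - start} bases, "
                "expected a single-base feature")
        if name in out:
            raise ParseError(f"{path} line {ln}: duplicate feature {name!r}")
        out[name] = GenomicPosition(chrom, start + 1)
    return out


def write_manifest(path: str | Path,
                   positions: Mapping[str, GenomicPosition]) -> None:
    lines = [f"{p.chrom}\t{p.pos - 1}\t{p.pos}\t{name}"
             for name, p in positions.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# covariates / phenotype

def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     na_values=[MISSING], keep_default_na=False)
    missing = [c for c in COVARIATE_COLUMNS + CELL_TYPES if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing covariate columns {missing}")
    return CovariateTable(df)


def write_covariates(path: str | Path, cov: CovariateTable) -> None:
    cols = list(COVARIATE_COLUMNS + CELL_TYPES)
    df = cov.data[cols]
    binary = {"sex", "ethnicity", "pregnancy_complications"}
    out_lines = ["\t".join(["sample_id"] + cols)]
    for sid, row in df.iterrows():
        toks = [str(sid)]
        for c in cols:
            v = row[c]
            if isinstance(v, str):
                toks.append(v)
            elif pd.isna(v):
                toks.append(MISSING)
            elif c in binary:
                toks.append(str(int(v)))
            else:
                toks.append(_fmt(float(v)))
        out_lines.append("\t".join(toks))
    Path(path).write_text("\n".join(out_lines) + "\n")


def read_phenotype(path: str | Path) -> tuple[PhenotypeVector, list[str]]:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    if list(df.columns) != ["sample_id", "tl"]:
        raise ParseError(f"{path}: expected columns sample_id, tl")
    return PhenotypeVector(df["tl"].to_numpy(dtype=float)), df["sample_id"].astype(str).tolist()


def write_phenotype(path: str | Path, pheno: PhenotypeVector,
                    sample_ids: list[str]) -> None:
    lines = ["sample_id\ttl"]
    lines += [f"{sid}\t{_fmt(v)}" for sid, v in zip(sample_ids, pheno.tl)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dataset bundle

def read_dataset(directory: str | Path) -> StudyDataset:
    """Assemble a StudyDataset from the standard file bundle in a directory."""
    d = Path(directory)
    snps = read_genotypes(d / "genotypes.tsv")
    cpgs = read_methylation(d / "methylation.tsv")
    cpg_manifest = read_manifest(d / "cpg_manifest.bed")
    cpgs = attach_positions(cpgs, cpg_manifest)
    cov = read_covariates(d / "covariates.tsv")
    pheno, sample_ids = read_phenotype(d / "phenotype.tsv")
    return StudyDataset(snps, cpgs, cov, pheno, sample_ids)


def write_dataset(directory: str | Path, ds: StudyDataset) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_genotypes(d / "genotypes.tsv", ds.snps, ds.sample_ids)
    write_vcf(d / "genotypes.vcf", ds.snps, ds.sample_ids)
    write_matrix(d / "methylation.tsv", ds.mvalue_matrix())
    write_manifest(d / "snp_manifest.bed",
                   {s.id: s.position for s in ds.snps})
    write_manifest(d / "cpg_manifest.bed",
                   {c.id: c.position for c in ds.cpgs})
    if ds.covariates is not None:
        write_covariates(d / "covariates.tsv", ds.covariates)
    write_phenotype(d / "phenotype.tsv", ds.phenotype, ds.sample_ids)
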