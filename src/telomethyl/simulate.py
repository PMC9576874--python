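"""Synthetic birth-cohort generator with known ground truth.

No individual-level data from the motivating cohort are deposited (only
allele-frequency summaries), so every stage of the pipeline is exercised on
synthetic cohorts that emulate the study's data structure: a small panel of
candidate SNPs drawn under Hardy-Weinberg equilibrium, cis CpG methylation
driven by a 7-component cord-blood cell mixture plus mQTL effects, batch
and array-position technical effects, detection failures and missingness,
the published covariate margins, and a T/S-ratio telomere phenotype
carrying direct, CpG-mediated and SNP-by-CpG interaction effects.

The generative phenotype model is

    TL = tl_mean + sum_p [c'_p * dom(SNP_p) + b_p * M_p]          (paths)
        + sum_s beta_s * dosage_s                                  (additive)
        + sum_c beta_c * M_c                                       (CpG main)
        + sum_i beta12_i * dosage_i * M_i                          (interaction)
        + covariate effects + N(0, tl_sd^2)

with every effect regressor centred at its realized mean so that
``tl_mean`` remains the cohort mean regardless of effect sizes (centring
shifts only the intercept; the slopes downstream models recover are
untouched).  Mediation-path effects use dominant coding and interaction /
additive main effects use allele counts, matching the coding each analysis
step applies, so fitted estimates are directly comparable to the stored
truth.  Technical batch effects are applied on top of the latent
(biologically effective) M-values; the phenotype responds to the latent
values.

Every generator is deterministic under a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, io
from .datamodel import (
    CELL_TYPES,
    CovariateTable,
    CpGRecord,
    GenomicPosition,
    PhenotypeVector,
    SNPRecord,
    StudyDataset,
)
from .methylation_qc import CellReferenceMatrix


@dataclass
class SNPSpec:
    id: str
    chrom: str
    pos: int
    maf: float
    major: str = "A"
    minor: str = "G"


@dataclass
class CpGSpec:
    id: str
    chrom: str
    pos: int
    baseline_mean: float = 0.0   # probe-level mean M-value
    is_reference: bool = False   # cell-type discriminating probe


@dataclass
class MediationPathSpec:
    """A SNP -> CpG -> TL path: a on dominant SNP, b on M, c' direct."""
    snp_id: str
    cpg_id: str
    a: float
    b: float
    c_prime: float


@dataclass
class SimulationConfig:
    n_samples: int = 281
    snp_spec: list[SNPSpec] = field(default_factory=list)
    cpg_spec: list[CpGSpec] = field(default_factory=list)
    mqtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    mediation_paths: list[MediationPathSpec] = field(default_factory=list)
    interaction_terms: list[tuple[str, str, float]] = field(default_factory=list)
    snp_effects_additive: list[tuple[str, float]] = field(default_factory=list)
    cpg_effects: list[tuple[str, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    tl_mean: float = 1.03            # cohort T/S mean
    tl_sd: float = 0.20              # residual T/S SD
    cell_model: bool = True
    cell_dirichlet_alpha: tuple = (2.8, 22.0, 2.8, 1.6, 2.0, 5.2, 3.6)
    cell_reference_sd: float = 0.2   # cell-type spread at non-reference probes
    cpg_noise_sd: float = 0.15       # residual M-value noise
    n_batches: int = 4
    n_positions: int = 8
    batch_shift_sd: float = 0.08
    batch_scale_sd: float = 0.05
    position_shift_sd: float = 0.04
    position_scale_sd: float = 0.02
    missing_rate_geno: float = 0.02
    missing_rate_meth: float = 0.005
    detection_fail_rate: float = 0.003
    cis_window_bp: int = 500_000
    seed: int = 0

    def snp(self, snp_id: str) -> SNPSpec:
        for s in self.snp_spec:
            if s.id == snp_id:
                return s
        raise KeyError(snp_id)

    def cpg(self, cpg_id: str) -> CpGSpec:
        for c in self.cpg_spec:
            if c.id == cpg_id:
                return c
        raise KeyError(cpg_id)

    def validate(self) -> list[str]:
        problems = []
        snp_ids = {s.id for s in self.snp_spec}
        cpg_ids = {c.id for c in self.cpg_spec}
        if len(snp_ids) != len(self.snp_spec):
            problems.append("duplicate SNP IDs in snp_spec")
        if len(cpg_ids) != len(self.cpg_spec):
            problems.append("duplicate CpG IDs in cpg_spec")
        for s in self.snp_spec:
            if not 0 < s.maf <= 0.5:
                problems.append(f"SNP {s.id}: maf {s.maf} outside (0, 0.5]")
        for rate_name in ("missing_rate_geno", "missing_rate_meth",
                          "detection_fail_rate"):
            v = getattr(self, rate_name)
            if not 0 <= v < 1:
                problems.append(f"{rate_name}={v} outside [0,1)")
        if self.tl_sd <= 0:
            problems.append("tl_sd must be > 0")
        if len(self.cell_dirichlet_alpha) != len(CELL_TYPES):
            problems.append("cell_dirichlet_alpha must have 7 entries")
        pair_lists = ([(p[0], p[1]) for p in self.mqtl_effects]
                      + [(p.snp_id, p.cpg_id) for p in self.mediation_paths]
                      + [(p[0], p[1]) for p in self.interaction_terms])
        for snp_id, cpg_id in pair_lists:
            if snp_id not in snp_ids:
                problems.append(f"effect references unknown SNP {snp_id}")
                continue
            if cpg_id not in cpg_ids:
                problems.append(f"effect references unknown CpG {cpg_id}")
                continue
            s, c = self.snp(snp_id), self.cpg(cpg_id)
            if s.chrom != c.chrom or abs(c.pos - s.pos) > self.cis_window_bp:
                problems.append(
                    f"effect pair {snp_id}-{cpg_id} lies outside the cis window")
        for snp_id, _ in self.snp_effects_additive:
            if snp_id not in snp_ids:
                problems.append(f"snp_effects_additive references unknown SNP {snp_id}")
        for cpg_id, _ in self.cpg_effects:
            if cpg_id not in cpg_ids:
                problems.append(f"cpg_effects references unknown CpG {cpg_id}")
        return problems


@dataclass
class GroundTruth:
    """Realized generative parameters and latent per-sample values."""

    config: dict
    latent_dosages: pd.DataFrame          # SNPs x samples, no missingness
    latent_mvalues: pd.DataFrame          # probes x samples, pre-batch
    true_cell_proportions: pd.DataFrame | None
    batch: pd.Series | None
    position: pd.Series | None
    path_effects: pd.DataFrame            # a, b, c_prime, ie, te per path

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "latent_dosages": _frame_payload(self.latent_dosages),
            "latent_mvalues": _frame_payload(self.latent_mvalues),
            "true_cell_proportions": (
                None if self.true_cell_proportions is None
                else _frame_payload(self.true_cell_proportions)),
            "batch": None if self.batch is None else self.batch.tolist(),
            "position": None if self.position is None else self.position.tolist(),
            "path_effects": _frame_payload(self.path_effects),
        }
        Path(path).write_text(json.dumps(payload))


def _frame_payload(df: pd.DataFrame) -> dict:
    return {"index": [str(i) for i in df.index],
            "columns": [str(c) for c in df.columns],
            "values": df.to_numpy().tolist()}


# ---------------------------------------------------------------------------
# default study-shaped configuration

_CIS_OFFSETS = (-420_000, -250_000, -120_000, -30_000,
                15_000, 80_000, 240_000, 460_000)
_BASELINE_CYCLE = (-3.2, 3.1, -0.4, 2.6, -2.8, 0.2, 3.4, -1.9)
#: CpGs named after the study's featured probes, keyed by their SNP partner
#: (all placed at the +15 kb cis offset).
_FEATURED_CPGS = {
    "rs4764600": "cg07142400",   # top mQTL pair
    "rs2535913": "cg12610013",   # mediation pair with same-sign DE/IE
    "rs911847": "cg24223887",    # interaction pair
    "rs2841505": "cg01064902",   # replicated mQTL
    "rs412658": "cg22620746",    # replicated mQTL
}


def default_simulation_config(seed: int = 0, n_samples: int = 281
                              ) -> SimulationConfig:
    """A cohort-shaped default: the 26-SNP panel, 8 cis CpGs per SNP,
    100 reference probes, and the published effect sizes as truth.

    MAFs are not published; representative common-variant values in
    [0.05, 0.45] are assigned deterministically per SNP.
    """
    snp_spec = []
    for i, (rsid, (pos, major, minor, _gene)) in enumerate(cohort.SNP_PANEL.items()):
        maf = round(0.05 + 0.40 * ((i * 0.61803398875) % 1.0), 3)
        snp_spec.append(SNPSpec(rsid, pos.chrom, pos.pos, maf, major, minor))

    cpg_spec = []
    counter = 0
    for rsid, (pos, _, _, _gene) in cohort.SNP_PANEL.items():
        if rsid == "rs755017":
            continue  # the panel SNP with no CpG in its 0.5 Mb neighbourhood
        for k, off in enumerate(_CIS_OFFSETS):
            cpg_pos = pos.pos + off
            if cpg_pos < 1:
                cpg_pos = pos.pos + abs(off)
            if off == 15_000 and rsid in _FEATURED_CPGS:
                cid = _FEATURED_CPGS[rsid]
                base = 3.3 if rsid == "rs911847" else _BASELINE_CYCLE[k]
            else:
                cid = f"cg{70000000 + counter:08d}"
                base = _BASELINE_CYCLE[k]
            counter += 1
            cpg_spec.append(CpGSpec(cid, pos.chrom, cpg_pos, base))
    # cell-type reference probes on a chromosome without panel SNPs
    for j in range(100):
        cpg_spec.append(CpGSpec(f"cg{80000000 + j:08d}", "chr21",
                                5_000_000 + 10_000 * j, 0.0, is_reference=True))

    return SimulationConfig(
        n_samples=n_samples,
        snp_spec=snp_spec,
        cpg_spec=cpg_spec,
        mqtl_effects=[
            ("rs4764600", "cg07142400", 0.50),
            ("rs2841505", "cg01064902", 0.35),
            ("rs412658", "cg22620746", 0.30),
        ],
        mediation_paths=[
            MediationPathSpec("rs2535913", "cg12610013", a=0.8, b=0.25,
                              c_prime=0.1),
        ],
        interaction_terms=[("rs911847", "cg24223887", -0.330)],
        snp_effects_additive=[("rs911847", 1.186)],
        cpg_effects=[("cg24223887", 0.263)],
        covariate_effects={"gestational_age": 0.005, "birth_weight": 0.02},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generators

def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator
                       ) -> tuple[list[SNPRecord], pd.DataFrame]:
    """Draw dosages i.i.d. Binomial(2, maf) per SNP (HWE by construction),
    then mask at ``missing_rate_geno``.

    Returns (records with missingness, latent complete dosage matrix).
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    records, latent_rows = [], []
    for spec in cfg.snp_spec:
        d = rng.binomial(2, spec.maf, size=cfg.n_samples).astype(float)
        latent_rows.append(d.copy())
        obs = d.copy()
        if cfg.missing_rate_geno > 0:
            mask = rng.random(cfg.n_samples) < cfg.missing_rate_geno
            obs[mask] = np.nan
        pos = GenomicPosition(spec.chrom, spec.pos)
        records.append(SNPRecord.from_dosages(spec.id, pos, spec.major,
                                              spec.minor, obs))
    latent = pd.DataFrame(np.vstack(latent_rows) if latent_rows else
                          np.empty((0, cfg.n_samples)),
                          index=[s.id for s in cfg.snp_spec], columns=sample_ids)
    return records, latent


def _dominant(d: np.ndarray) -> np.ndarray:
    return (d > 0).astype(float)


def simulate_methylation(cfg: SimulationConfig, latent_dosages: pd.DataFrame,
                         rng: np.random.Generator) -> dict:
    """Generate methylation with cell-mixture structure and technical effects.

    Returns a dict with keys ``cpgs`` (records with missingness applied),
    ``reference`` (CellReferenceMatrix), ``detection_p`` (DataFrame),
    ``batch``/``position`` (Series), ``latent_mvalues`` (pre-batch),
    ``proportions`` (true cell proportions or None).
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("; ".join(problems))
    n = cfg.n_samples
    sample_ids = list(latent_dosages.columns)
    probe_ids = [c.id for c in cfg.cpg_spec]
    G = len(probe_ids)

    # mQTL-type effects per probe (per-allele, plus dominant path a-effects)
    effect_add: dict[str, list[tuple[str, float]]] = {}
    for snp_id, cpg_id, beta in cfg.mqtl_effects:
        effect_add.setdefault(cpg_id, []).append((snp_id, beta))
    effect_dom: dict[str, list[tuple[str, float]]] = {}
    for p in cfg.mediation_paths:
        effect_dom.setdefault(p.cpg_id, []).append((p.snp_id, p.a))

    proportions = None
    ref_rows: dict[str, np.ndarray] = {}
    M = np.empty((G, n))
    if cfg.cell_model:
        alpha = np.asarray(cfg.cell_dirichlet_alpha, dtype=float)
        W = rng.dirichlet(alpha, size=n)  # n x 7
        proportions = pd.DataFrame(W, index=sample_ids, columns=list(CELL_TYPES))
    for g, spec in enumerate(cfg.cpg_spec):
        if cfg.cell_model:
            if spec.is_reference:
                # one discriminating cell type per reference probe
                t = g % len(CELL_TYPES)
                row = rng.normal(0.0, 0.6, size=len(CELL_TYPES))
                row[t] += (2.5 + rng.random()) * (1 if g % 2 == 0 else -1)
                row += spec.baseline_mean
                ref_rows[spec.id] = row
            else:
                row = spec.baseline_mean + rng.normal(
                    0.0, cfg.cell_reference_sd, size=len(CELL_TYPES))
            base = W @ row
        else:
            base = np.full(n, spec.baseline_mean)
        m = base + rng.normal(0.0, cfg.cpg_noise_sd, size=n)
        for snp_id, beta in effect_add.get(spec.id, ()):
            m = m + beta * latent_dosages.loc[snp_id].to_numpy()
        for snp_id, a in effect_dom.get(spec.id, ()):
            m = m + a * _dominant(latent_dosages.loc[snp_id].to_numpy())
        M[g] = m

    latent = pd.DataFrame(M.copy(), index=probe_ids, columns=sample_ids)

    batch = position = None
    if cfg.cell_model:
        batch = pd.Series(rng.integers(cfg.n_batches, size=n), index=sample_ids,
                          name="batch")
        position = pd.Series(rng.integers(cfg.n_positions, size=n),
                             index=sample_ids, name="position")
        probe_means = M.mean(axis=1, keepdims=True)
        for labels, shift_sd, scale_sd, n_levels in (
                (batch, cfg.batch_shift_sd, cfg.batch_scale_sd, cfg.n_batches),
                (position, cfg.position_shift_sd, cfg.position_scale_sd,
                 cfg.n_positions)):
            shifts = rng.normal(0.0, shift_sd, size=(G, n_levels))
            scales = np.exp(rng.normal(0.0, scale_sd, size=(G, n_levels)))
            lab = labels.to_numpy()
            M = probe_means + shifts[:, lab] + scales[:, lab] * (M - probe_means)

    # detection failures and missingness
    detection = np.zeros((G, n))
    if cfg.detection_fail_rate > 0:
        fail = rng.random((G, n)) < cfg.detection_fail_rate
        detection[fail] = rng.uniform(1e-8, 1.0, size=int(fail.sum()))
    if cfg.missing_rate_meth > 0:
        miss = rng.random((G, n)) < cfg.missing_rate_meth
        M = np.where(miss, np.nan, M)

    cpgs = [CpGRecord(spec.id, GenomicPosition(spec.chrom, spec.pos), M[g])
            for g, spec in enumerate(cfg.cpg_spec)]
    reference = None
    if ref_rows:
        reference = CellReferenceMatrix(pd.DataFrame.from_dict(
            ref_rows, orient="index", columns=list(CELL_TYPES)))
    return {
        "cpgs": cpgs,
        "reference": reference,
        "detection_p": pd.DataFrame(detection, index=probe_ids,
                                    columns=sample_ids),
        "batch": batch,
        "position": position,
        "latent_mvalues": latent,
        "proportions": proportions,
    }


def simulate_covariates(cfg: SimulationConfig,
                        proportions: pd.DataFrame | None,
                        rng: np.random.Generator) -> CovariateTable:
    """Draw covariates from the published cohort margins (independent
    marginals; the joint dependence is not modelled)."""
    n = cfg.n_samples
    idx = (proportions.index if proportions is not None
           else [f"S{i + 1:04d}" for i in range(n)])
    data = {}
    data["sex"] = rng.binomial(1, cohort.category_probabilities("sex")["male"], n)
    data["ethnicity"] = rng.binomial(
        1, cohort.category_probabilities("ethnicity")["non_european"], n)
    data["pregnancy_complications"] = rng.binomial(
        1, cohort.category_probabilities("pregnancy_complications")["yes"], n)
    for col, margin_key in (("gestational_age", "gestational_age"),
                            ("birth_weight", "birth_weight"),
                            ("pre_pregnancy_bmi", "pre_pregnancy_bmi"),
                            ("paternal_age", "paternal_age")):
        mean, sd = cohort.CONTINUOUS_MARGINS[margin_key]
        data[col] = rng.normal(mean, sd, n)
    for col in ("parity", "education", "smoking"):
        probs = cohort.category_probabilities(col)
        levels = list(probs)
        data[col] = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    df = pd.DataFrame(data, index=pd.Index(idx, name="sample_id"))
    if proportions is not None:
        for ct in CELL_TYPES:
            df[ct] = proportions[ct].to_numpy()
    else:
        for ct, a in zip(CELL_TYPES, cfg.cell_dirichlet_alpha):
            df[ct] = a / sum(cfg.cell_dirichlet_alpha)
    return CovariateTable(df)


def simulate_phenotype(cfg: SimulationConfig, latent_dosages: pd.DataFrame,
                       latent_mvalues: pd.DataFrame,
                       covariates: CovariateTable | None,
                       rng: np.random.Generator
                       ) -> tuple[PhenotypeVector, pd.DataFrame]:
    """Generate T/S-ratio telomere length from the structural model.

    Returns (phenotype, path-effects table with the true a, b, c', ie = a*b
    and te = c' + a*b per mediation path).
    """
    n = cfg.n_samples
    tl = np.full(n, cfg.tl_mean, dtype=float)

    def centred(x: np.ndarray) -> np.ndarray:
        return x - x.mean()

    rows = []
    for p in cfg.mediation_paths:
        dom = _dominant(latent_dosages.loc[p.snp_id].to_numpy())
        m = latent_mvalues.loc[p.cpg_id].to_numpy()
        tl += p.c_prime * centred(dom) + p.b * centred(m)
        rows.append((p.snp_id, p.cpg_id, p.a, p.b, p.c_prime,
                     p.a * p.b, p.c_prime + p.a * p.b))
    for snp_id, beta in cfg.snp_effects_additive:
        tl += beta * centred(latent_dosages.loc[snp_id].to_numpy())
    for cpg_id, beta in cfg.cpg_effects:
        tl += beta * centred(latent_mvalues.loc[cpg_id].to_numpy())
    for snp_id, cpg_id, beta12 in cfg.interaction_terms:
        d = latent_dosages.loc[snp_id].to_numpy()
        m = latent_mvalues.loc[cpg_id].to_numpy()
        tl += beta12 * centred(d * m)
    if covariates is not None:
        for col, beta in cfg.covariate_effects.items():
            tl += beta * centred(covariates.data[col].to_numpy(dtype=float))
    tl += rng.normal(0.0, cfg.tl_sd, size=n)
    paths = pd.DataFrame(rows, columns=["snp_id", "cpg_id", "a", "b",
                                        "c_prime", "ie", "te"])
    return PhenotypeVector(tl), paths


def simulate_study(cfg: SimulationConfig, out_dir: str | Path | None = None
                   ) -> tuple[StudyDataset, GroundTruth, dict]:
    """Generate a full study bundle; optionally write it to disk.

    Returns (dataset, ground truth, extras) where ``extras`` carries the
    detection-p matrix, batch/position labels and the cell reference.
    Re-reading a written bundle yields a valid StudyDataset; identical
    seeds produce byte-identical output files.
    """
    problems = cfg.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    rng = np.random.default_rng(cfg.seed)
    snps, latent_d = simulate_genotypes(cfg, rng)
    meth = simulate_methylation(cfg, latent_d, rng)
    cov = simulate_covariates(cfg, meth["proportions"], rng)
    pheno, paths = simulate_phenotype(cfg, latent_d, meth["latent_mvalues"],
                                      cov, rng)
    sample_ids = list(latent_d.columns)
    ds = StudyDataset(snps, meth["cpgs"], cov, pheno, sample_ids)
    truth = GroundTruth(
        config=_config_payload(cfg),
        latent_dosages=latent_d,
        latent_mvalues=meth["latent_mvalues"],
        true_cell_proportions=meth["proportions"],
        batch=meth["batch"],
        position=meth["position"],
        path_effects=paths,
    )
    extras = {"detection_p": meth["detection_p"], "batch": meth["batch"],
              "position": meth["position"], "reference": meth["reference"]}
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        io.write_dataset(d, ds)
        io.write_matrix(d / "detection_p.tsv", meth["detection_p"])
        if meth["batch"] is not None:
            tech = pd.DataFrame({"batch": meth["batch"],
                                 "position": meth["position"]})
            tech.index.name = "sample_id"
            tech.to_csv(d / "technical.tsv", sep="\t")
        if meth["reference"] is not None:
            io.write_matrix(d / "cell_reference.tsv", meth["reference"].data)
        truth.to_json(d / "truth.json")
    return ds, truth, extras


def _config_payload(cfg: SimulationConfig) -> dict:
    payload = asdict(cfg)
    payload["cell_dirichlet_alpha"] = list(cfg.cell_dirichlet_alpha)
    return payload
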