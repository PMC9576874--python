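"""Analysis configuration: every QC/inference threshold in one flat record.

Defaults are the study protocol's values; a YAML file can override any of
them, so each constant is discoverable and adjustable without code changes.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    cis_window_bp: int = 500_000        # +/- window defining cis SNP-CpG pairs
    alpha: float = 0.05                 # nominal / family-wise significance level
    n_boot: int = 1_000                 # bootstrap replicates for mediation CIs
    snp_call_rate_min: float = 0.95     # SNPs below this non-missing fraction are dropped
    sample_call_rate_min_geno: float = 0.90
    maf_min: float = 0.01               # strict: maf < maf_min is dropped
    hwe_p_min: float = 0.05             # strict: HWE p < hwe_p_min is dropped
    probe_call_rate_min: float = 0.95
    detection_p_max: float = 1e-16      # a call with detection p above this fails
    sample_call_rate_min_meth: float = 0.99
    knn_k: int = 10
    iqr_factor: float = 3.0
    seed: int = 0
    # interpretation switches (see docs/methods.md)
    mqtl_both_codings: bool = True      # mQTL set = dominant AND additive significant
    n_snp_main_tests: int = 26          # Bonferroni m for SNP main effects in step 4

    def validate(self) -> list[str]:
        problems = []
        for name in ("snp_call_rate_min", "sample_call_rate_min_geno",
                     "probe_call_rate_min", "sample_call_rate_min_meth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name}={v} outside [0,1]")
        if not 0 <= self.maf_min <= 0.5:
            problems.append(f"maf_min={self.maf_min} outside [0,0.5]")
        if not 0 < self.alpha < 1:
            problems.append(f"alpha={self.alpha} outside (0,1)")
        if not 0 <= self.hwe_p_min <= 1:
            problems.append(f"hwe_p_min={self.hwe_p_min} outside [0,1]")
        if self.cis_window_bp < 0:
            problems.append("cis_window_bp must be >= 0")
        if self.n_boot < 1:
            problems.append("n_boot must be >= 1")
        if self.knn_k < 1:
            problems.append("knn_k must be >= 1")
        if self.iqr_factor <= 0:
            problems.append("iqr_factor must be > 0")
        if not 0 < self.detection_p_max < 1:
            problems.append("detection_p_max outside (0,1)")
        return problems

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        problems = cfg.validate()
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
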