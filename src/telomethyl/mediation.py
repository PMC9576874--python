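"""Step 3: causal mediation of the SNP-telomere association by methylation.

The path model assumes genotype (fixed at conception) precedes methylation,
which precedes telomere-length determination.  With a dominant-coded SNP X,
mediator CpG M and outcome TL, two linear models are fitted:

    mediator:  M  ~ X + C        ->  a   (SNP -> CpG)
    outcome:   TL ~ X + M + C    ->  c' (direct effect), b (CpG -> TL)

The indirect effect is the product IE = a*b, the direct effect DE = c',
and the total effect TE = DE + IE.  In linear models without a
treatment-mediator interaction this product-of-coefficients IE coincides
with the causal ACME, and TE equals the coefficient of X in TL ~ X + C
(the difference method) — an identity the test suite asserts.

The proportion mediated IE/TE is reported only when DE and IE share a
sign (otherwise it is not interpretable and left undefined).

Inference is nonparametric bootstrap over individuals: resample rows with
replacement, refit both models, and take 2.5/97.5 percentile CIs per
effect; the bootstrap p-value is the symmetric two-sided percentile form
2*min(P(effect <= 0), P(effect >= 0)).  Replicates in which the resampled
SNP or mediator is constant are redrawn and counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import StudyDataset
from .genotype_qc import code_genotypes
from .linmod import build_design, fit_ols
from .scans import MQTLScan

CANDIDATE_COLUMNS = ["snp_id", "cpg_id", "mqtl_p", "cpg_tl_p"]

_EFFECTS = ("a", "b", "de", "ie", "te")


@dataclass
class MediationPoint:
    snp_id: str
    cpg_id: str
    a: float
    b: float
    de: float
    ie: float
    te: float
    prop_mediated: float | None


@dataclass
class MediationResult:
    point: MediationPoint
    ci: dict[str, tuple[float, float]]
    boot_p: dict[str, float]
    prop_ci: tuple[float, float] | None
    prop_p: float | None
    n_same_sign_replicates: int
    n_boot: int
    seed: int
    n_degenerate_redrawn: int

    def to_row(self) -> dict:
        p = self.point
        row = {"snp_id": p.snp_id, "cpg_id": p.cpg_id, "a": p.a, "b": p.b,
               "de": p.de, "ie": p.ie, "te": p.te,
               "prop_mediated": np.nan if p.prop_mediated is None else p.prop_mediated}
        for eff in _EFFECTS:
            row[f"{eff}_ci_lo"], row[f"{eff}_ci_hi"] = self.ci[eff]
            row[f"{eff}_boot_p"] = self.boot_p[eff]
        row["prop_ci_lo"], row["prop_ci_hi"] = (
            self.prop_ci if self.prop_ci is not None else (np.nan, np.nan))
        row["prop_boot_p"] = np.nan if self.prop_p is None else self.prop_p
        row["n_same_sign_replicates"] = self.n_same_sign_replicates
        row["n_boot"] = self.n_boot
        row["seed"] = self.seed
        row["n_degenerate_redrawn"] = self.n_degenerate_redrawn
        return row


def select_candidates(mqtl: MQTLScan, dataset: StudyDataset,
                      alpha: float = 0.05,
                      adjust_for_snp: bool = False) -> pd.DataFrame:
    """Mediator candidates: CpGs in a significant mQTL that also associate
    with telomere length at nominal ``alpha``.

    The TL ~ CpG screen is marginal (covariate-adjusted, no SNP) by
    default; ``adjust_for_snp=True`` conditions on the pair's SNP.  A CpG
    significant with k SNPs yields k candidate pairs.
    """
    if mqtl.significant_pairs.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    base = build_design(dataset.covariates, n_samples=dataset.n_samples)
    y = dataset.phenotype.tl
    dom = mqtl.results[mqtl.results["coding"] == "dominant"].set_index(
        ["snp_id", "cpg_id"])
    rows = []
    cpg_p_cache: dict[str, float] = {}
    for _, pair in mqtl.significant_pairs.iterrows():
        snp_id, cpg_id = pair["snp_id"], pair["cpg_id"]
        m = dataset.cpg(cpg_id).mvalues
        if adjust_for_snp:
            coded = code_genotypes(dataset.snp(snp_id), "dominant")
            fit = fit_ols(base.with_columns({"cpg": m, "snp": coded.values}), y)
            p_tl = fit.coef_named("cpg")[3]
        else:
            if cpg_id not in cpg_p_cache:
                fit = fit_ols(base.with_columns({"cpg": m}), y)
                cpg_p_cache[cpg_id] = fit.coef_named("cpg")[3]
            p_tl = cpg_p_cache[cpg_id]
        if p_tl < alpha:
            mqtl_p = float(dom.loc[(snp_id, cpg_id), "p"]) \
                if (snp_id, cpg_id) in dom.index else np.nan
            rows.append((snp_id, cpg_id, mqtl_p, p_tl))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def _prepare(dataset: StudyDataset, snp_id: str, cpg_id: str
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Assemble (X_mediator, X_outcome, m, y, idx_snp, idx_cpg) once.

    Column layouts: mediator design [... covariates ..., snp];
    outcome design [... covariates ..., snp, cpg].
    """
    coded = code_genotypes(dataset.snp(snp_id), "dominant")
    if coded.is_constant:
        raise ValueError(f"constant dominant-coded SNP {snp_id}")
    m = dataset.cpg(cpg_id).mvalues
    if np.ptp(m) == 0:
        raise ValueError(f"constant CpG {cpg_id}")
    if np.isnan(m).any() or np.isnan(dataset.phenotype.tl).any():
        raise ValueError("missing values; complete data required")
    base = build_design(dataset.covariates, n_samples=dataset.n_samples)
    X_med = base.with_columns({"snp": coded.values})
    X_out = X_med.with_columns({"cpg": m})
    i_snp = X_out.names.index("snp")
    i_cpg = X_out.names.index("cpg")
    return X_med.X, X_out.X, m, dataset.phenotype.tl, i_snp, i_cpg


def _point_estimates(X_med: np.ndarray, X_out: np.ndarray, m: np.ndarray,
                     y: np.ndarray, i_snp: int, i_cpg: int
                     ) -> tuple[float, float, float]:
    """(a, b, c') from the two least-squares fits."""
    beta_med, *_ = np.linalg.lstsq(X_med, m, rcond=None)
    beta_out, *_ = np.linalg.lstsq(X_out, y, rcond=None)
    return float(beta_med[i_snp]), float(beta_out[i_cpg]), float(beta_out[i_snp])


def fit_mediation(dataset: StudyDataset, snp_id: str, cpg_id: str
                  ) -> MediationPoint:
    """Point estimates of a, b, DE, IE, TE and the proportion mediated."""
    X_med, X_out, m, y, i_snp, i_cpg = _prepare(dataset, snp_id, cpg_id)
    a, b, c_prime = _point_estimates(X_med, X_out, m, y, i_snp, i_cpg)
    ie = a * b
    te = c_prime + ie
    prop = ie / te if np.sign(c_prime) == np.sign(ie) and te != 0 else None
    return MediationPoint(snp_id, cpg_id, a, b, c_prime, ie, te, prop)


def bootstrap_mediation(dataset: StudyDataset, snp_id: str, cpg_id: str,
                        n_boot: int = 1_000, seed: int = 0,
                        max_degenerate_frac: float = 0.10) -> MediationResult:
    """Bootstrap-percentile inference for the mediation decomposition.

    Individuals are resampled with replacement, preserving the covariate
    joint distribution; both models are refitted per replicate.
    Deterministic under ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = fit_mediation(dataset, snp_id, cpg_id)
    X_med, X_out, m, y, i_snp, i_cpg = _prepare(dataset, snp_id, cpg_id)
    n = len(y)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))  # a, b, c'
    n_degenerate = 0
    max_degenerate = int(np.ceil(max_degenerate_frac * n_boot))
    snp_col = X_med[:, i_snp]
    for r in range(n_boot):
        while True:
            idx = rng.integers(n, size=n)
            if np.ptp(snp_col[idx]) > 0 and np.ptp(m[idx]) > 0:
                break
            n_degenerate += 1
            if n_degenerate > max_degenerate:
                raise ValueError(
                    f"more than {max_degenerate_frac:.0%} degenerate bootstrap "
                    "replicates; data too sparse")
        draws[r] = _point_estimates(X_med[idx], X_out[idx], m[idx], y[idx],
                                    i_snp, i_cpg)
    a_s, b_s, c_s = draws[:, 0], draws[:, 1], draws[:, 2]
    ie_s = a_s * b_s
    te_s = c_s + ie_s
    samples = {"a": a_s, "b": b_s, "de": c_s, "ie": ie_s, "te": te_s}
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in samples.items()}
    boot_p = {k: _percentile_p(v) for k, v in samples.items()}
    same_sign = np.sign(c_s) == np.sign(ie_s)
    n_same = int(same_sign.sum())
    if point.prop_mediated is not None and n_same > 0:
        prop_s = ie_s[same_sign] / te_s[same_sign]
        prop_ci = (float(np.percentile(prop_s, 2.5)),
                   float(np.percentile(prop_s, 97.5)))
        prop_p = _percentile_p(prop_s)
    else:
        prop_ci, prop_p = None, None
    return MediationResult(point, ci, boot_p, prop_ci, prop_p, n_same,
                           n_boot, seed, n_degenerate)


def _percentile_p(samples: np.ndarray) -> float:
    """Symmetric two-sided bootstrap percentile p-value for H0: effect = 0."""
    frac_le = np.mean(samples <= 0)
    frac_ge = np.mean(samples >= 0)
    return float(min(1.0, 2.0 * min(frac_le, frac_ge)))


def mediate_candidates(dataset: StudyDataset, candidates: pd.DataFrame,
                       n_boot: int = 1_000, seed: int = 0) -> pd.DataFrame:
    """Bootstrap mediation for every candidate pair; tidy result table."""
    rows = []
    for i, (_, cand) in enumerate(candidates.iterrows()):
        res = bootstrap_mediation(dataset, cand["snp_id"], cand["cpg_id"],
                                  n_boot=n_boot, seed=seed + i)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
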