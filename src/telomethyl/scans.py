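"""Association scans: SNP-telomere, cis-mQTL, and SNP-by-CpG interaction.

Step 1 regresses cord-blood telomere length (T/S ratio) on each SNP in a
covariate-adjusted multiple regression, under dominant and additive coding.

Step 2 maps cis-mQTLs: for every SNP-CpG pair within the +/-0.5 Mb window,
the CpG M-value is regressed on the coded SNP with covariate adjustment;
residual variances are moderated across pairs by the empirical-Bayes
shrinkage in :mod:`telomethyl.linmod`, and family-wise error is controlled
by Bonferroni over all tested pairs.  The reported significant set requires
significance under both codings (configurable to the union).

Step 4 fits, for every cis pair NOT in the significant-mQTL set (the
exclusion avoids collinearity between the SNP and its own mQTL target),

    TL = b0 + b1*SNP + b2*CpG + b12*SNP*CpG + C'gamma + eps

with additive SNP coding; b12 is Bonferroni-controlled over the
interaction universe and b1 separately over the SNP panel size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CpGRecord, SNPRecord, StudyDataset
from .genotype_qc import code_genotypes
from .linmod import (
    DesignMatrix,
    ModerationParams,
    bonferroni,
    build_design,
    ebayes_moderate,
    fit_ols,
    fit_ols_multi,
    moderated_pvalues,
)

ASSOCIATION_COLUMNS = ["snp_id", "coding", "beta", "se", "t", "p", "n",
                       "significant", "untestable"]
MQTL_COLUMNS = ["snp_id", "cpg_id", "coding", "distance_bp", "beta", "se",
                "t_moderated", "p", "bonferroni_significant"]
INTERACTION_COLUMNS = ["snp_id", "cpg_id", "distance_bp",
                       "beta12", "se12", "p12",
                       "beta_snp", "p_snp", "beta_cpg", "p_cpg", "n",
                       "interaction_bonferroni", "snp_main_bonferroni"]


def enumerate_cis_pairs(snps: list[SNPRecord], cpgs: list[CpGRecord],
                        window_bp: int = 500_000) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs with |distance| <= window (inclusive).

    Distance is signed as CpG position minus SNP position.
    """
    cpg_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for c in cpgs:
        cpg_by_chrom.setdefault(c.position.chrom, []).append((c.position.pos, c.id))
    for lst in cpg_by_chrom.values():
        lst.sort()
    rows = []
    for s in snps:
        near = cpg_by_chrom.get(s.position.chrom, [])
        if not near:
            continue
        positions = np.array([p for p, _ in near])
        lo = np.searchsorted(positions, s.position.pos - window_bp, side="left")
        hi = np.searchsorted(positions, s.position.pos + window_bp, side="right")
        for pos, cid in near[lo:hi]:
            rows.append((s.id, cid, pos - s.position.pos))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance_bp"])


def scan_tl_snp(dataset: StudyDataset, coding: str = "dominant",
                alpha: float = 0.05) -> pd.DataFrame:
    """Step 1: one covariate-adjusted OLS of TL on each coded SNP.

    Nominal significance at ``alpha``; constant coded genotypes are
    reported as untestable with NaN estimates.
    """
    design = build_design(dataset.covariates, n_samples=dataset.n_samples)
    y = dataset.phenotype.tl
    rows = []
    for snp in dataset.snps:
        coded = code_genotypes(snp, coding)
        if coded.is_constant:
            rows.append((snp.id, coding, np.nan, np.nan, np.nan, np.nan,
                         dataset.n_samples, False, True))
            continue
        fit = fit_ols(design.with_columns({"snp": coded.values}), y)
        beta, se, t, p = fit.coef_named("snp")
        rows.append((snp.id, coding, beta, se, t, p, fit.n, p < alpha, False))
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


@dataclass
class MQTLScan:
    results: pd.DataFrame                    # one row per pair per coding
    significant_pairs: pd.DataFrame          # pairs in the reported mQTL set
    m_tests: int                             # pairs per coding (Bonferroni m)
    threshold: float
    moderation: dict[str, ModerationParams]  # per coding


def scan_mqtl(dataset: StudyDataset, window_bp: int = 500_000,
              alpha: float = 0.05, require_both_codings: bool = True,
              moderate: bool = True,
              codings: tuple[str, ...] = ("dominant", "additive")) -> MQTLScan:
    """Step 2: cis-mQTL scan with empirical-Bayes moderated inference.

    All CpGs cis to one SNP share that SNP's design, so they are fitted as
    one multi-response OLS; variances are then moderated jointly across
    every tested pair of a coding (they share the residual df).  With
    ``moderate=False`` ordinary t inference is used (the d0 = 0 path).
    """
    pairs = enumerate_cis_pairs(dataset.snps, dataset.cpgs, window_bp)
    if pairs.empty:
        return MQTLScan(pd.DataFrame(columns=MQTL_COLUMNS),
                        pd.DataFrame(columns=["snp_id", "cpg_id"]),
                        0, np.nan, {})
    base_design = build_design(dataset.covariates, n_samples=dataset.n_samples)
    mmat = dataset.mvalue_matrix()
    m_tests = len(pairs)
    all_results = []
    moderation: dict[str, ModerationParams] = {}
    sig_sets: dict[str, set[tuple[str, str]]] = {}
    for coding in codings:
        recs = []  # (snp, cpg, dist, beta, se, t, s2, df)
        for snp_id, grp in pairs.groupby("snp_id", sort=False):
            snp = dataset.snp(snp_id)
            coded = code_genotypes(snp, coding)
            if coded.is_constant:
                raise ValueError(f"constant coded genotype for {snp_id}; QC first")
            design = base_design.with_columns({"snp": coded.values})
            Y = mmat.loc[grp["cpg_id"]].to_numpy().T  # n x m
            if np.isnan(Y).any():
                raise ValueError("missing M-values; run methylation QC first")
            beta, se, s2, df = fit_ols_multi(design.X, Y)
            j = design.names.index("snp")
            for i, (_, row) in enumerate(grp.iterrows()):
                recs.append((snp_id, row["cpg_id"], row["distance_bp"],
                             beta[j, i], se[j, i], s2[i], df))
        rec = pd.DataFrame(recs, columns=["snp_id", "cpg_id", "distance_bp",
                                          "beta", "se", "s2", "df"])
        t_ord = rec["beta"] / rec["se"]
        df = int(rec["df"].iloc[0])
        if moderate and len(rec) < 10:
            moderate = False  # too few pairs to fit a variance prior
        if moderate:
            params, _s2t, mult = ebayes_moderate(rec["s2"].to_numpy(), df)
            t_mod, p = moderated_pvalues(t_ord.to_numpy(), mult, df, params.d0)
        else:
            from scipy import stats
            params = ModerationParams(0.0, float("nan"))
            t_mod = t_ord.to_numpy()
            p = 2.0 * stats.t.sf(np.abs(t_mod), df)
        moderation[coding] = params
        flags, threshold = bonferroni(p, alpha)
        out = pd.DataFrame({
            "snp_id": rec["snp_id"], "cpg_id": rec["cpg_id"],
            "coding": coding, "distance_bp": rec["distance_bp"],
            "beta": rec["beta"], "se": rec["se"], "t_moderated": t_mod,
            "p": p, "bonferroni_significant": flags,
        })
        all_results.append(out)
        sig_sets[coding] = set(map(tuple, out.loc[flags, ["snp_id", "cpg_id"]]
                                   .itertuples(index=False)))
    results = pd.concat(all_results, ignore_index=True)[MQTL_COLUMNS]
    sets = list(sig_sets.values())
    sig = set.intersection(*sets) if require_both_codings else set.union(*sets)
    sig_df = (pd.DataFrame(sorted(sig), columns=["snp_id", "cpg_id"])
              if sig else pd.DataFrame(columns=["snp_id", "cpg_id"]))
    return MQTLScan(results, sig_df, m_tests, alpha / m_tests, moderation)


def compare_to_reference(significant_pairs: pd.DataFrame,
                         results: pd.DataFrame,
                         reference: pd.DataFrame) -> pd.DataFrame:
    """Match significant mQTL pairs against a published reference table.

    ``reference`` has columns snp_id, cpg_id, ref_beta (its sign is the
    reference direction).  Each pair is classified as
    ``replicated_concordant``, ``replicated_discordant`` or ``novel``.
    Direction of this study's estimate is the sign of the additive-coding
    beta (falling back to dominant when additive is absent).
    """
    if not {"snp_id", "cpg_id", "ref_beta"} <= set(reference.columns):
        raise ValueError("reference needs snp_id, cpg_id, ref_beta columns")
    ref = reference.drop_duplicates(["snp_id", "cpg_id"]).set_index(
        ["snp_id", "cpg_id"])
    rows = []
    for _, pair in significant_pairs.iterrows():
        key = (pair["snp_id"], pair["cpg_id"])
        sub = results[(results["snp_id"] == key[0])
                      & (results["cpg_id"] == key[1])]
        prefer = sub[sub["coding"] == "additive"]
        beta = float((prefer if len(prefer) else sub)["beta"].iloc[0])
        if key in ref.index:
            ref_beta = float(ref.loc[key, "ref_beta"])
            status = ("replicated_concordant"
                      if np.sign(beta) == np.sign(ref_beta)
                      else "replicated_discordant")
        else:
            ref_beta, status = np.nan, "novel"
        rows.append((key[0], key[1], beta, ref_beta, status))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "beta",
                                       "ref_beta", "status"])


def scan_interaction(dataset: StudyDataset,
                     mqtl_significant_pairs: pd.DataFrame | None = None,
                     window_bp: int = 500_000, alpha: float = 0.05,
                     n_snp_main_tests: int | None = None) -> pd.DataFrame:
    """Step 4: SNP-by-CpG effect-modification scan.

    The tested universe is every cis pair minus the significant mQTL pairs
    (whose genotype and methylation cannot be assumed independent).  SNPs
    are additive coded.  The interaction term is Bonferroni-controlled over
    the universe size; the SNP main effect over ``n_snp_main_tests``
    (defaults to the SNP panel size).
    """
    pairs = enumerate_cis_pairs(dataset.snps, dataset.cpgs, window_bp)
    if mqtl_significant_pairs is not None and len(mqtl_significant_pairs):
        excluded = set(map(tuple, mqtl_significant_pairs[["snp_id", "cpg_id"]]
                           .itertuples(index=False)))
        keep = [t not in excluded for t in
                pairs[["snp_id", "cpg_id"]].itertuples(index=False, name=None)]
        pairs = pairs.loc[keep]
    if pairs.empty:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    if n_snp_main_tests is None:
        n_snp_main_tests = len(dataset.snps)
    base_design = build_design(dataset.covariates, n_samples=dataset.n_samples)
    mmat = dataset.mvalue_matrix()
    y = dataset.phenotype.tl
    rows = []
    for snp_id, grp in pairs.groupby("snp_id", sort=False):
        coded = code_genotypes(dataset.snp(snp_id), "additive")
        for _, pr in grp.iterrows():
            m = mmat.loc[pr["cpg_id"]].to_numpy()
            design = base_design.with_columns({
                "snp": coded.values, "cpg": m, "snp_x_cpg": coded.values * m})
            fit = fit_ols(design, y)
            b12, se12, _, p12 = fit.coef_named("snp_x_cpg")
            b1, _, _, p1 = fit.coef_named("snp")
            b2, _, _, p2 = fit.coef_named("cpg")
            rows.append((snp_id, pr["cpg_id"], pr["distance_bp"],
                         b12, se12, p12, b1, p1, b2, p2, fit.n))
    out = pd.DataFrame(rows, columns=INTERACTION_COLUMNS[:-2])
    m_inter = len(out)
    out["interaction_bonferroni"] = out["p12"] <= alpha / m_inter
    out["snp_main_bonferroni"] = out["p_snp"] <= alpha / n_snp_main_tests
    return out[INTERACTION_COLUMNS]
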