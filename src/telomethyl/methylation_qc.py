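"""Methylation preprocessing chain.

Order is fixed and mirrors the array-processing protocol:

    detection filter -> (M-values, if starting from intensities)
    -> KNN imputation -> empirical-Bayes batch/position adjustment
    -> 3-IQR outlier trimming -> blacklist filter
    -> reference-based cell-type deconvolution

Matrices are probes-x-samples :class:`pandas.DataFrame` objects throughout,
with NaN marking missing calls.

The batch adjustment is the parametric location/scale empirical-Bayes
method used for microarray batch correction: per probe, standardize to the
pooled mean/variance, estimate per-batch location (gamma) and scale
(delta^2), shrink them toward method-of-moments priors (normal on gamma,
inverse-gamma on delta^2) via the iterative posterior solution, remove the
shrunken effects and restore the pooled scale.  Batch and position are
adjusted sequentially.

Cell-type deconvolution is constrained projection: per sample solve
``min ||R w - m||^2  s.t.  w >= 0`` against the cell-type reference matrix
R, then rescale w to sum to one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datamodel import CELL_TYPES, GenomicPosition


@dataclass
class MethylationQCReport:
    probes_dropped_detection: list[str] = field(default_factory=list)
    samples_dropped_call_rate: list[str] = field(default_factory=list)
    probes_dropped_blacklist: list[str] = field(default_factory=list)
    values_trimmed_count: int = 0
    imputed_count: int = 0


@dataclass
class CellReferenceMatrix:
    """Cell-type mean M-values at discriminating probes (probes x 7 types)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(CELL_TYPES):
            raise ValueError(f"reference columns must be {CELL_TYPES}")
        if self.data.isna().any().any():
            raise ValueError("reference matrix has missing entries")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)


def mvalue_transform(meth_intensity: np.ndarray, unmeth_intensity: np.ndarray,
                     offset: float = 1.0) -> np.ndarray:
    """M = log2((meth + offset) / (unmeth + offset)).

    The offset keeps the ratio defined at zero intensity; negative
    intensities are rejected.
    """
    meth = np.asarray(meth_intensity, dtype=float)
    unmeth = np.asarray(unmeth_intensity, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("negative intensity")
    return np.log2((meth + offset) / (unmeth + offset))


def detection_filter(mvalues: pd.DataFrame, detection_p: pd.DataFrame,
                     probe_call_rate_min: float = 0.95,
                     sample_call_rate_min: float = 0.99,
                     detection_p_max: float = 1e-16,
                     report: MethylationQCReport | None = None,
                     ) -> tuple[pd.DataFrame, MethylationQCReport]:
    """Drop poorly detected probes, then poorly detected samples.

    A call fails when its detection p-value exceeds ``detection_p_max``.
    Probes with call rate < ``probe_call_rate_min`` are dropped first;
    samples with call rate (over retained probes) < ``sample_call_rate_min``
    second; failed calls that survive both filters become missing.
    """
    report = report or MethylationQCReport()
    if not mvalues.index.equals(detection_p.index) or \
            not mvalues.columns.equals(detection_p.columns):
        raise ValueError("M-value and detection-p matrices are not co-indexed")
    failed = detection_p.to_numpy() > detection_p_max
    probe_cr = 1.0 - failed.mean(axis=1)
    keep_probes = probe_cr >= probe_call_rate_min
    report.probes_dropped_detection = list(mvalues.index[~keep_probes])
    m = mvalues.loc[keep_probes]
    failed = failed[keep_probes]
    sample_cr = 1.0 - failed.mean(axis=0) if len(m) else np.ones(m.shape[1])
    keep_samples = sample_cr >= sample_call_rate_min
    report.samples_dropped_call_rate = list(m.columns[~keep_samples])
    m = m.loc[:, keep_samples].copy()
    failed = failed[:, keep_samples]
    vals = m.to_numpy(dtype=float)
    vals[failed] = np.nan
    return pd.DataFrame(vals, index=m.index, columns=m.columns), report


def knn_impute(matrix: pd.DataFrame, k: int = 10,
               report: MethylationQCReport | None = None) -> pd.DataFrame:
    """Probe-wise K-nearest-neighbour imputation.

    For each missing entry, the k nearest probes (Euclidean distance over
    co-observed samples, squared distance averaged over the number of
    co-observed columns; ties broken by row order) supply the mean of
    their values in that sample.  Neighbours themselves missing there are
    skipped; if none remain the probe's own row mean is used.  Observed
    entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.to_numpy(dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return matrix.copy()
    if mask.all(axis=1).any():
        bad = matrix.index[mask.all(axis=1)].tolist()
        raise ValueError(f"probes with no observed values: {bad}")
    G = X.shape[0]
    # mean squared difference over co-observed columns, pairwise
    Xz = np.where(mask, 0.0, X)
    obs = (~mask).astype(float)
    co_counts = obs @ obs.T
    sq = (Xz ** 2) @ obs.T + obs @ (Xz ** 2).T - 2.0 * (Xz @ Xz.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(co_counts > 0, sq / co_counts, np.inf)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)  # guard tiny negative round-off
    row_means = np.nanmean(X, axis=1)
    out = X.copy()
    order_cache: dict[int, np.ndarray] = {}
    for g in np.nonzero(mask.any(axis=1))[0]:
        if g not in order_cache:
            order_cache[g] = np.argsort(d2[g], kind="stable")
        neighbors = order_cache[g][:k]
        neighbors = neighbors[np.isfinite(d2[g][neighbors])]
        for j in np.nonzero(mask[g])[0]:
            donor_vals = X[neighbors, j]
            donor_vals = donor_vals[~np.isnan(donor_vals)]
            out[g, j] = donor_vals.mean() if donor_vals.size else row_means[g]
    if report is not None:
        report.imputed_count += int(mask.sum())
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def eb_batch_adjust(matrix: pd.DataFrame, factor_labels: Iterable,
                    conv: float = 1e-4, max_iter: int = 200) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment (one factor).

    Requires a complete matrix (run after imputation), >= 2 factor levels
    and >= 2 samples per level.  The probe-wise pooled mean is preserved.
    """
    labels = np.asarray(list(factor_labels))
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values; impute before batch adjustment")
    if labels.size != X.shape[1]:
        raise ValueError("factor labels do not match the sample count")
    levels, inverse = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        return matrix.copy()
    counts = np.bincount(inverse)
    for lvl, c in zip(levels, counts):
        if c < 2:
            raise ValueError(f"factor level {lvl!r} has a single sample")
    G, N = X.shape
    if G < 2:
        raise ValueError("need >= 2 probes")

    # per-probe batch means, grand mean and pooled residual variance
    batch_means = np.stack([X[:, inverse == i].mean(axis=1)
                            for i in range(len(levels))], axis=1)  # G x I
    grand_mean = batch_means @ (counts / N)
    fitted = batch_means[:, inverse]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    Z = (X - grand_mean[:, None]) / sd[:, None]

    Z_adj = Z.copy()
    for i, lvl in enumerate(levels):
        idx = inverse == i
        n_i = int(counts[i])
        Zi = Z[:, idx]
        gamma_hat = Zi.mean(axis=1)
        delta_hat = Zi.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar = gamma_hat.mean()
        tau_sq = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 <= 0:
            gamma_star = gamma_hat if tau_sq <= 0 else (
                (n_i * tau_sq * gamma_hat + delta_hat * gamma_bar)
                / (n_i * tau_sq + delta_hat))
            delta_star = delta_hat
        else:
            a_prior = (2 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
            g_old, d_old = gamma_hat.copy(), delta_hat.copy()
            for _ in range(max_iter):
                g_new = ((n_i * tau_sq * gamma_hat + d_old * gamma_bar)
                         / (n_i * tau_sq + d_old))
                sum2 = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
                change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                             np.max(np.abs(d_new - d_old) / d_old))
                g_old, d_old = g_new, d_new
                if change < conv:
                    break
            gamma_star, delta_star = g_old, d_old
        Z_adj[:, idx] = (Zi - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = Z_adj * sd[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def remove_technical_effects(matrix: pd.DataFrame, batch: Iterable,
                             position: Iterable | None = None) -> pd.DataFrame:
    """Sequential EB adjustment: batch first, then array position."""
    out = eb_batch_adjust(matrix, batch)
    if position is not None:
        out = eb_batch_adjust(out, position)
    return out


def iqr_trim(matrix: pd.DataFrame, factor: float = 3.0,
             report: MethylationQCReport | None = None
             ) -> tuple[pd.DataFrame, int]:
    """Set per-probe outliers outside [Q1 - f*IQR, Q3 + f*IQR] to missing.

    Quartiles use linear interpolation and are computed once (single pass,
    not recomputed after removal).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    X = matrix.to_numpy(dtype=float)
    q1 = np.nanpercentile(X, 25, axis=1)
    q3 = np.nanpercentile(X, 75, axis=1)
    iqr = q3 - q1
    lo = (q1 - factor * iqr)[:, None]
    hi = (q3 + factor * iqr)[:, None]
    with np.errstate(invalid="ignore"):
        outliers = (X < lo) | (X > hi)
    count = int(outliers.sum())
    out = X.copy()
    out[outliers] = np.nan
    if report is not None:
        report.values_trimmed_count += count
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), count


def blacklist_filter(matrix: pd.DataFrame,
                     positions: Mapping[str, GenomicPosition] | None = None,
                     sex_chromosomes: set[str] = frozenset({"chrX", "chrY"}),
                     snp_probes: set[str] = frozenset(),
                     cross_reactive_probes: set[str] = frozenset(),
                     report: MethylationQCReport | None = None,
                     ) -> pd.DataFrame:
    """Remove probes on sex chromosomes, at common SNPs, or cross-reactive."""
    blacklist = set(snp_probes) | set(cross_reactive_probes)
    if positions is not None:
        blacklist |= {pid for pid, pos in positions.items()
                      if pos.chrom in sex_chromosomes}
    keep = [pid for pid in matrix.index if pid not in blacklist]
    dropped = [pid for pid in matrix.index if pid in blacklist]
    if report is not None:
        report.probes_dropped_blacklist = dropped
    return matrix.loc[keep]


def estimate_cell_proportions(mvalues: pd.DataFrame,
                              reference: CellReferenceMatrix) -> pd.DataFrame:
    """Constrained-projection cell-type deconvolution.

    Per sample, solve non-negative least squares against the reference and
    rescale the weights to sum to one.  Output rows sum to 1 within 1e-9.
    """
    ref = reference.data
    missing = [p for p in ref.index if p not in mvalues.index]
    if missing:
        raise ValueError(f"reference probes absent from matrix: {missing[:5]}...")
    R = ref.to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValueError("reference matrix is rank deficient")
    M = mvalues.loc[ref.index].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing values at reference probes; impute first")
    out = np.empty((M.shape[1], len(CELL_TYPES)))
    for j in range(M.shape[1]):
        w, _ = nnls(R, M[:, j])
        total = w.sum()
        out[j] = w / total if total > 0 else np.full(len(CELL_TYPES),
                                                     1.0 / len(CELL_TYPES))
    return pd.DataFrame(out, index=mvalues.columns, columns=list(CELL_TYPES))


def run_methylation_qc(mvalues: pd.DataFrame, detection_p: pd.DataFrame,
                       batch: Iterable, position: Iterable | None,
                       reference: CellReferenceMatrix,
                       positions: Mapping[str, GenomicPosition] | None = None,
                       snp_probes: set[str] = frozenset(),
                       cross_reactive_probes: set[str] = frozenset(),
                       probe_call_rate_min: float = 0.95,
                       sample_call_rate_min: float = 0.99,
                       detection_p_max: float = 1e-16,
                       knn_k: int = 10, iqr_factor: float = 3.0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, MethylationQCReport]:
    """The full chain in protocol order.

    Returns (clean M-value matrix, estimated cell proportions, report).
    The returned matrix has been detection-filtered, imputed, batch/position
    adjusted, trimmed (trimmed entries re-imputed so downstream models see
    complete data) and blacklist filtered.
    """
    report = MethylationQCReport()
    batch = np.asarray(list(batch))
    position_arr = None if position is None else np.asarray(list(position))
    m, report = detection_filter(mvalues, detection_p, probe_call_rate_min,
                                 sample_call_rate_min, detection_p_max, report)
    keep = [c for c in mvalues.columns if c in m.columns]
    sample_mask = np.isin(np.asarray(mvalues.columns), keep)
    batch = batch[sample_mask]
    if position_arr is not None:
        position_arr = position_arr[sample_mask]
    m = knn_impute(m, knn_k, report)
    m = remove_technical_effects(m, batch, position_arr)
    m, _ = iqr_trim(m, iqr_factor, report)
    if m.isna().any().any():
        m = knn_impute(m, knn_k)
    m = blacklist_filter(m, positions,
                         snp_probes=snp_probes,
                         cross_reactive_probes=cross_reactive_probes,
                         report=report)
    # reference probes lost to the detection filter are dropped from the
    # reference as well; deconvolution needs a comfortable surplus of probes
    surviving = [p for p in reference.probe_ids if p in m.index]
    if len(surviving) < 2 * len(CELL_TYPES):
        raise ValueError("too few reference probes survive QC for deconvolution")
    ref = CellReferenceMatrix(reference.data.loc[surviving])
    proportions = estimate_cell_proportions(m, ref)
    return m, proportions, report
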